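"""Match model-derived motifs against external RBP motif libraries.

Motifs are exchanged in MEME minimal format.  The similarity between two
PWMs is the best gapless-alignment mean per-column Pearson correlation;
significance comes from a seeded column-permutation test (positions of the
target PWM are shuffled and the best similarity recomputed).  MEME export
is provided so an external comparison tool can be run on the same motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .interpret import Pwm


@dataclass
class ExternalMotif:
    name: str
    pwm: Pwm
    source: str = ""


class MemeFormatError(ValueError):
    pass


def read_meme(path) -> list[ExternalMotif]:
    """Parse MEME minimal format; ACGT alphabets are relabeled to ACGU.
    Rows off unit sum by more than 1e-3 are renormalized with a warning;
    a truncated matrix block is an error."""
    motifs: list[ExternalMotif] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            source = parts[2] if len(parts) > 2 else ""
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                    "letter-probability"):
                if lines[j].strip().startswith("MOTIF"):
                    raise MemeFormatError(f"motif {name}: no probability matrix")
                j += 1
            if j >= len(lines):
                raise MemeFormatError(f"motif {name}: no probability matrix")
            header = lines[j]
            w = None
            for tok_k, tok_v in zip(header.split(), header.split()[1:]):
                if tok_k == "w=":
                    w = int(tok_v)
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
                j += 1
            if w is not None and len(rows) < w:
                raise MemeFormatError(
                    f"motif {name}: truncated matrix ({len(rows)} of {w} rows)")
            if not rows:
                raise MemeFormatError(f"motif {name}: empty probability matrix")
            m = np.array(rows)
            sums = m.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                warnings.warn(f"motif {name}: rows off unit sum, renormalizing")
            m = m / sums[:, None]
            motifs.append(ExternalMotif(name, Pwm(m, source=name), source))
            i = j
        else:
            i += 1
    return motifs


def write_meme(path, motifs, alphabet: str = "ACGU"):
    """Write PWMs (Pwm, ExternalMotif, or (name, Pwm)) in MEME minimal
    format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= %s\n\n" % alphabet)
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} 0.25000" for a in alphabet) + "\n\n")
        for item in motifs:
            if isinstance(item, ExternalMotif):
                name, pwm = item.name, item.pwm
            elif isinstance(item, Pwm):
                name, pwm = item.source or "motif", item
            else:
                name, pwm = item
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {max(pwm.n_subsequences, 1)} E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def _column_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each aligned column pair (rows of width x 4 blocks);
    zero-variance columns contribute 0 by convention."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac * ac).sum(axis=1))
    nb = np.sqrt((bc * bc).sum(axis=1))
    denom = na * nb
    num = (ac * bc).sum(axis=1)
    out = np.zeros(len(a))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def compare_pwms(query: Pwm, target: Pwm, min_overlap: int = 4):
    """Best gapless alignment of two PWMs.

    Offset is the position of the target start relative to the query start;
    similarity is the mean per-column Pearson correlation over the
    overlapping columns.  Returns (best_offset, best_similarity).
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    wq, wt = query.width, target.width
    if min(wq, wt) < min_overlap:
        raise ValueError("PWMs too short for the requested overlap")
    best = (None, -np.inf)
    for off in range(-(wt - min_overlap), wq - min_overlap + 1):
        qs, ts = max(0, off), max(0, -off)
        n = min(wq - qs, wt - ts)
        if n < min_overlap:
            continue
        sim = float(_column_pearson(query.matrix[qs : qs + n],
                                    target.matrix[ts : ts + n]).mean())
        if sim > best[1] or (sim == best[1] and best[0] is not None
                             and (abs(off), off) < (abs(best[0]), best[0])):
            best = (off, sim)
    if best[0] is None:
        raise ValueError("no alignment satisfies min_overlap")
    return best


def match_significance(query: Pwm, target: Pwm, similarity: float | None = None,
                       n_perm: int = 999, seed: int = 0,
                       min_overlap: int = 4) -> float:
    """Permutation p-value for a PWM match: the null shuffles the target's
    column (position) order ``n_perm`` times and recomputes the best
    similarity; p = (1 + #null >= observed) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if similarity is None:
        _, similarity = compare_pwms(query, target, min_overlap)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(target.width)
        null_t = Pwm(target.matrix[perm])
        _, s = compare_pwms(query, null_t, min_overlap)
        if s >= similarity:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def match_all(queries, targets, alpha: float = 0.01, n_perm: int = 999,
              seed: int = 0, min_overlap: int = 4) -> pd.DataFrame:
    """Score every (query, target) pair; rows sorted by p ascending with a
    per-query Benjamini-Hochberg column alongside the raw p, and pairs
    with raw p < alpha flagged significant."""
    rows = []
    for qi, q in enumerate(queries):
        if isinstance(q, tuple):
            qid, qpwm = q
        else:
            qid, qpwm = (q.source or f"query_{qi}"), q
        for ti, t in enumerate(targets):
            if isinstance(t, ExternalMotif):
                tname, tpwm = t.name, t.pwm
            elif isinstance(t, tuple):
                tname, tpwm = t
            else:
                tname, tpwm = (t.source or f"target_{ti}"), t
            off, sim = compare_pwms(qpwm, tpwm, min_overlap)
            p = match_significance(qpwm, tpwm, sim, n_perm,
                                   seed=seed + 7919 * qi + ti, min_overlap=min_overlap)
            rows.append(dict(query_id=qid, target_name=tname, offset=off,
                             orientation="forward", similarity=sim, p_value=p))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = np.nan
        for qid, grp in df.groupby("query_id"):
            df.loc[grp.index, "q_value"] = false_discovery_control(
                grp["p_value"].to_numpy())
        df["significant"] = df["p_value"] < alpha
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return df
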