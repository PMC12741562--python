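"""Variant effect scanning on predicted modification probability.

For each single-nucleotide variant, every U position within one window
flank of the variant (on either allele) is scored before and after the
substitution, and the change is classified:

* ``loss``    — the center U itself is replaced (ref U, alt not U) and the
  reference window scores at or above ``threshold``;
* ``gain``    — the alt allele creates a center U that scores at or above
  ``threshold``, or an unchanged center U crosses the threshold upward;
* ``altered`` — the center U is retained on both alleles and |delta| is at
  least ``delta_min``;
* ``none``    — everything else.

Categories are mutually exclusive with precedence loss > gain > altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import SequenceWindow, normalize_rna

CATEGORIES = ("loss", "gain", "altered", "none")


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str


class RefMismatchError(ValueError):
    pass


def read_vcf(path):
    """Read SNVs from a VCF; indels are skipped and counted.

    Returns (variants, n_skipped_indels).  Alleles are normalized to the
    RNA alphabet.
    """
    from pysam import VariantFile

    variants, skipped = [], 0
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt in ("*", "<NON_REF>"):
                    skipped += 1
                    continue
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                variants.append(Variant(vid, rec.chrom, rec.pos - 1,
                                        normalize_rna(rec.ref),
                                        normalize_rna(alt)))
    return variants, skipped


def _window_at(seq: str, pos: int, flank: int) -> str | None:
    lo, hi = pos - flank, pos + flank + 1
    if lo < 0 or hi > len(seq):
        return None
    return seq[lo:hi]


def scan_variants(trained, genome, variants, flank: int = 20,
                  threshold: float = 0.5, delta_min: float = 0.1
                  ) -> pd.DataFrame:
    """Score every U within ±flank of each SNV on both alleles.

    ``trained`` is anything with a ``predict(windows) -> scores`` method;
    ``genome`` maps chrom -> RNA sequence.  A variant whose ref allele
    mismatches the genome raises ``RefMismatchError``.  Truncated windows
    near contig ends are skipped.
    """
    rows = []
    jobs = []  # (row template, ref window, alt window)
    for v in variants:
        if v.chrom not in genome:
            raise KeyError(f"chromosome {v.chrom!r} absent from genome")
        seq = genome[v.chrom]
        if seq[v.position] != v.ref:
            raise RefMismatchError(
                f"variant {v.id}: genome has {seq[v.position]!r} at "
                f"{v.chrom}:{v.position}, VCF ref is {v.ref!r}")
        alt_seq = seq[: v.position] + v.alt + seq[v.position + 1 :]
        for p in range(max(0, v.position - flank),
                       min(len(seq), v.position + flank + 1)):
            if seq[p] != "U" and alt_seq[p] != "U":
                continue
            w_ref = _window_at(seq, p, flank)
            w_alt = _window_at(alt_seq, p, flank)
            if w_ref is None or w_alt is None:
                continue
            jobs.append((v, p, w_ref, w_alt))
    if not jobs:
        return pd.DataFrame(columns=[
            "variant", "chrom", "position", "ref_center", "alt_center",
            "score_ref", "score_alt", "delta", "category"])
    all_windows = [SequenceWindow(w) for _, _, wr, wa in jobs for w in (wr, wa)]
    scores = np.asarray(trained.predict(all_windows), dtype=float)
    for i, (v, p, w_ref, w_alt) in enumerate(jobs):
        s_ref, s_alt = scores[2 * i], scores[2 * i + 1]
        delta = float(s_alt - s_ref)
        ref_c, alt_c = w_ref[flank], w_alt[flank]
        if ref_c == "U" and alt_c != "U":
            cat = "loss" if s_ref >= threshold else "none"
        elif ref_c != "U" and alt_c == "U":
            cat = "gain" if s_alt >= threshold else "none"
        else:  # U retained on both alleles
            if s_ref < threshold <= s_alt:
                cat = "gain"
            elif abs(delta) >= delta_min:
                cat = "altered"
            else:
                cat = "none"
        rows.append(dict(variant=v.id, chrom=v.chrom, position=p,
                         ref_center=ref_c, alt_center=alt_c,
                         score_ref=float(s_ref), score_alt=float(s_alt),
                         delta=delta, category=cat))
    return pd.DataFrame(rows)


def summarize_categories(table: pd.DataFrame) -> dict[str, int]:
    """Counts per category (all four keys always present)."""
    counts = {c: 0 for c in CATEGORIES}
    if len(table):
        counts.update(table["category"].value_counts().to_dict())
    return counts
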