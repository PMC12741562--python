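"""Training/testing dataset construction and reproducible splits.

Two construction recipes are covered: balanced U-centered datasets (every
experimentally mapped site is a positive; negatives are unmodified
U-centered windows sampled to match the positive count) and 1:5
consensus-constrained datasets (candidate negatives are RRACH centers in
exons, minus anything inside a known modification peak, sampled so the
5'UTR/CDS/3'UTR proportions match the positives by largest-remainder
rounding).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field

import numpy as np
from intervaltree import IntervalTree
from sklearn.model_selection import StratifiedKFold, train_test_split

from .seqio import GenomicSite, PeakInterval, SequenceWindow, extract_window

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: the canonical m6A context: R R A C H, methylated A at index 2
RRACH = "RRACH"


@dataclass
class DatasetSpec:
    flank: int = 20
    ratio_neg_per_pos: float = 1.0
    region_match: bool = False
    seed: int = 42
    exclusion_peaks: list = field(default_factory=list)
    motif_constraint: str | None = None

    def __post_init__(self):
        if self.ratio_neg_per_pos <= 0:
            raise ValueError("ratio must be positive")


def find_motif_sites(sequence: str, pattern: str = RRACH,
                     center_index: int | None = None) -> list[int]:
    """Center offsets of every (possibly overlapping) match of an
    IUPAC-class pattern; the pattern's center defaults to len//2
    (RRACH -> the A at index 2)."""
    bad = sorted({c for c in pattern if c not in IUPAC})
    if bad:
        raise ValueError(f"undefined IUPAC symbols {bad}")
    if center_index is None:
        center_index = len(pattern) // 2
    classes = [IUPAC[c] for c in pattern]
    m = len(pattern)
    out = []
    for start in range(len(sequence) - m + 1):
        if all(sequence[start + i] in classes[i] for i in range(m)):
            out.append(start + center_index)
    return out


def largest_remainder(proportions, total: int) -> list[int]:
    """Integer quotas summing to ``total`` proportional to ``proportions``
    (largest-remainder rounding; |quota - exact| <= 1 per cell)."""
    props = np.asarray(proportions, dtype=float)
    if props.sum() == 0:
        raise ValueError("all proportions zero")
    exact = props / props.sum() * total
    base = np.floor(exact).astype(int)
    rest = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rest]] += 1
    return base.tolist()


def _peak_index(peaks) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.chrom].addi(p.start, p.end, None)
    return trees


def build_m6a_negatives(candidates, peaks, positives, region_ratios,
                        n_target: int, seed: int = 42) -> list[GenomicSite]:
    """Sample negatives from candidate consensus centers.

    Candidates inside any peak (any overlap of the single base with the
    half-open interval) or coinciding with a positive are excluded; the
    survivors are sampled per region so counts match ``region_ratios``
    (e.g. the positive 5'UTR/CDS/3'UTR proportions) by largest-remainder
    rounding.  Deterministic for a seed.
    """
    trees = _peak_index(peaks)
    pos_keys = {(s.chrom, s.position, s.strand) for s in positives}
    survivors = [
        c for c in candidates
        if not trees.get(c.chrom, IntervalTree()).overlaps(c.position)
        and (c.chrom, c.position, c.strand) not in pos_keys
    ]
    if not survivors:
        raise ValueError("no candidate negatives survive peak/positive exclusion")
    regions = sorted(region_ratios)
    quotas = dict(zip(regions, largest_remainder(
        [region_ratios[r] for r in regions], n_target)))
    by_region: dict[str, list[GenomicSite]] = defaultdict(list)
    for c in survivors:
        by_region[c.region].append(c)
    rng = np.random.default_rng(seed)
    out: list[GenomicSite] = []
    for r in regions:
        pool = by_region.get(r, [])
        need = quotas[r]
        if len(pool) < need:
            raise ValueError(
                f"region {r}: need {need} negatives, only {len(pool)} candidates")
        idx = rng.choice(len(pool), size=need, replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out


def build_m5u_dataset(positives, genome, spec: DatasetSpec
                      ) -> list[SequenceWindow]:
    """Balanced (or ratio-matched) U-centered dataset.

    Positives become windows directly; negatives are unmodified U positions
    sampled from the genome/transcriptome sequences, excluding positive
    coordinates, ``count(positives) * ratio`` of them.  N-containing and
    truncated windows are dropped.
    """
    rng = np.random.default_rng(spec.seed)
    pos_keys = {(s.chrom, s.position) for s in positives}
    windows: list[SequenceWindow] = []
    for s in positives:
        w = extract_window(genome, s, spec.flank, drop_truncated=True)
        if w is None or w.has_n:
            continue
        w.label = 1
        windows.append(w)
    n_neg = int(round(len(windows) * spec.ratio_neg_per_pos))
    candidates = [
        (chrom, i)
        for chrom in sorted(genome)
        for i, b in enumerate(genome[chrom])
        if b == "U" and (chrom, i) not in pos_keys
        and spec.flank <= i < len(genome[chrom]) - spec.flank
    ]
    if len(candidates) < n_neg:
        raise ValueError(
            f"genome has only {len(candidates)} eligible U positions, "
            f"need {n_neg}")
    idx = rng.choice(len(candidates), size=n_neg, replace=False)
    for i in sorted(idx):
        chrom, pos = candidates[i]
        site = GenomicSite(chrom, pos, "+", label="negative")
        w = extract_window(genome, site, spec.flank, drop_truncated=True)
        if w is not None and not w.has_n:
            w.label = 0
            windows.append(w)
    return windows


@dataclass
class SplitManifest:
    train_ids: list
    test_ids: list
    fold_assignments: dict
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test overlap")

    def folds(self, k: int | None = None):
        """Iterate (fold, train_ids, heldout_ids) over the CV folds."""
        ks = sorted(set(self.fold_assignments.values()))
        for f in ks:
            held = [i for i in self.train_ids if self.fold_assignments[i] == f]
            rest = [i for i in self.train_ids if self.fold_assignments[i] != f]
            yield f, rest, held

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        d["fold_assignments"] = {
            (int(k) if k.lstrip("-").isdigit() else k): v
            for k, v in d["fold_assignments"].items()
        }
        return cls(**d)


def make_splits(ids, labels, test_fraction: float = 0.2, k: int = 10,
                seed: int = 42) -> SplitManifest:
    """Stratified train/test split plus k stratified CV folds over the
    training ids (fold sizes differ by at most one)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(ids)
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int))
    if np.any(counts[counts > 0] < k):
        raise ValueError(f"a class has fewer than k={k} members")
    tr_idx, te_idx = train_test_split(
        np.arange(len(ids)), test_size=test_fraction, stratify=labels,
        random_state=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    tr_labels = labels[tr_idx]
    for f, (_, held) in enumerate(skf.split(tr_idx, tr_labels)):
        for j in held:
            fold_of[ids[tr_idx[j]]] = f
    return SplitManifest(
        train_ids=[ids[i] for i in sorted(tr_idx)],
        test_ids=[ids[i] for i in sorted(te_idx)],
        fold_assignments=fold_of, seed=seed)
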