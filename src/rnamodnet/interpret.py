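"""Decode trained convolutional filters into sequence motifs.

A filter of width T scanning an L-nt window yields N = L - T + 1
activations.  Subsequences whose activation exceeds the filter's mean
activation (over all positions of all scanned positive-class windows) are
harvested and stacked into a position weight matrix.  A filter's motif
score M_s is the difference between the mean per-window maximum activation
on the positive and negative classes; significance comes from a two-sided
Mann-Whitney rank test on the per-window maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .encodings import BASES, _BASE_INDEX
from .network import Network
from .seqio import SequenceWindow


@dataclass
class Pwm:
    """Position weight matrix: ``matrix`` is width x 4 row-stochastic over
    (A, C, G, U); ``counts`` the integer base counts it was built from."""

    matrix: np.ndarray
    counts: np.ndarray | None = None
    source: str = ""
    n_subsequences: int = 0
    pseudocount: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        rowsum = self.matrix.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, consensus: str, strength: float = 0.91,
                       source: str = "") -> "Pwm":
        """Point-mass-ish PWM with ``strength`` on the consensus base and
        the rest spread uniformly."""
        off = (1.0 - strength) / 3.0
        m = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            m[i, _BASE_INDEX[b]] = strength
        return cls(m, source=source)


@dataclass
class MotifReport:
    filter_id: int
    pwm: Pwm | None
    motif_score: float
    mean_activation_pos: float
    mean_activation_neg: float
    p_value: float
    position_histogram: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_subsequences: int = 0


def scan_filter(trained: Network, windows, filter_id: int) -> np.ndarray:
    """Per-window pre-pooling ReLU activations of one filter, shape
    (n, N) with N = L - T + 1 and stride 1."""
    if not 0 <= filter_id < trained.config.conv_filters:
        raise KeyError(
            f"filter {filter_id} outside 0..{trained.config.conv_filters - 1}")
    return trained.conv_activations(windows)[:, :, filter_id]


def harvest_subsequences(activations: np.ndarray, windows,
                         threshold_rule: str = "mean"):
    """Extract T-length subsequences at every (window, offset) whose
    activation is strictly above the filter's mean activation.

    Returns (subsequences, offsets).  The mean is computed over all
    positions of all scanned windows; constant activations harvest nothing
    (with a warning).
    """
    if threshold_rule != "mean":
        raise ValueError("only the 'mean' threshold rule is defined")
    seqs = [w.sequence if isinstance(w, SequenceWindow) else str(w) for w in windows]
    acts = np.asarray(activations)
    if acts.shape[0] != len(seqs):
        raise ValueError("activations / windows length mismatch")
    T = len(seqs[0]) - acts.shape[1] + 1
    thr = acts.mean()
    rows, cols = np.nonzero(acts > thr)
    if rows.size == 0:
        warnings.warn("no activation above the mean; nothing harvested")
        return [], np.zeros(0, dtype=int)
    subs = [seqs[r][c : c + T] for r, c in zip(rows, cols)]
    return subs, cols


def build_pwm(subsequences, pseudocount: float = 0.5, source: str = "") -> Pwm:
    """Stack same-length subsequences into counts and a row-stochastic PWM
    with additive ``pseudocount`` per base."""
    subs = list(subsequences)
    if not subs:
        raise ValueError("no subsequences")
    T = len(subs[0])
    if any(len(s) != T for s in subs):
        raise ValueError("subsequences of mixed lengths")
    counts = np.zeros((T, 4))
    for s in subs:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    matrix = (counts + pseudocount) / (len(subs) + 4 * pseudocount)
    return Pwm(matrix, counts=counts, source=source,
               n_subsequences=len(subs), pseudocount=pseudocount)


def motif_score(trained: Network, filter_id: int, pos_windows, neg_windows,
                pseudocount: float = 0.5,
                activations: tuple[np.ndarray, np.ndarray] | None = None
                ) -> MotifReport:
    """Score one filter's class discrimination.

    The per-window statistic is the maximum activation over positions;
    M_s = mean(max) over positives - mean(max) over negatives, with a
    two-sided Mann-Whitney p-value on the per-window maxima.  The PWM and
    the activation-position histogram come from harvesting the positive
    class.
    """
    if len(pos_windows) == 0 or len(neg_windows) == 0:
        raise ValueError("both classes must be non-empty")
    if activations is None:
        acts_pos = scan_filter(trained, pos_windows, filter_id)
        acts_neg = scan_filter(trained, neg_windows, filter_id)
    else:
        acts_pos, acts_neg = activations
    max_pos = acts_pos.max(axis=1)
    max_neg = acts_neg.max(axis=1)
    ms = float(max_pos.mean() - max_neg.mean())
    if np.ptp(np.concatenate([max_pos, max_neg])) == 0:
        p = 1.0
    else:
        p = float(mannwhitneyu(max_pos, max_neg, alternative="two-sided").pvalue)
    subs, offsets = harvest_subsequences(acts_pos, pos_windows)
    N = acts_pos.shape[1]
    hist = np.bincount(offsets, minlength=N) if len(offsets) else np.zeros(N, int)
    pwm = (build_pwm(subs, pseudocount, source=f"filter_{filter_id}")
           if subs else None)
    return MotifReport(filter_id=filter_id, pwm=pwm, motif_score=ms,
                       mean_activation_pos=float(max_pos.mean()),
                       mean_activation_neg=float(max_neg.mean()),
                       p_value=p, position_histogram=hist,
                       n_subsequences=len(subs))


def motif_reports(trained: Network, pos_windows, neg_windows,
                  pseudocount: float = 0.5) -> list[MotifReport]:
    """MotifReport for every filter, sorted by M_s descending.  Activations
    are computed once for all filters."""
    acts_pos = trained.conv_activations(pos_windows)
    acts_neg = trained.conv_activations(neg_windows)
    reports = []
    for f in range(trained.config.conv_filters):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(
                motif_score(trained, f, pos_windows, neg_windows, pseudocount,
                            activations=(acts_pos[:, :, f], acts_neg[:, :, f])))
    reports.sort(key=lambda r: r.motif_score, reverse=True)
    return reports


def cluster_pwms(pwms, k: int | None = None, cut_height: float | None = None):
    """Average-linkage hierarchical clustering of equal-width PWMs under
    the distance 1 - Spearman correlation of the flattened matrices.

    Returns (labels, linkage) with 1-based cluster labels.
    """
    pwms = list(pwms)
    if len(pwms) < 2:
        raise ValueError("need at least two PWMs")
    widths = {p.width for p in pwms}
    if len(widths) != 1:
        raise ValueError(f"mixed PWM widths {sorted(widths)}; align first")
    flat = np.array([p.matrix.reshape(-1) for p in pwms])
    ranks = np.apply_along_axis(rankdata, 1, flat)
    rho = np.corrcoef(ranks)
    dist = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        raise ValueError("give k or cut_height")
    return labels, Z


def metagene_profile(sites, annotation, bins: int = 30):
    """Density of sites along the normalized 5'UTR-CDS-3'UTR metagene axis.

    Each site maps to a fractional position inside its region; the axis is
    [0,1) 5'UTR, [1,2) CDS, [2,3) 3'UTR with ``bins`` bins per region.
    Returns (bin_centers, density, n_skipped); the density integrates to 1
    over the axis.  Sites without a same-strand coding transcript are
    skipped and counted.
    """
    offsets = {"5UTR": 0.0, "CDS": 1.0, "3UTR": 2.0}
    xs = []
    skipped = 0
    for site in sites:
        region, frac = annotation.locate(site)
        if region not in offsets or not np.isfinite(frac):
            skipped += 1
            continue
        xs.append(offsets[region] + min(frac, 1.0 - 1e-9))
    edges = np.linspace(0.0, 3.0, 3 * bins + 1)
    counts, _ = np.histogram(xs, bins=edges)
    width = 3.0 / (3 * bins)
    total = counts.sum()
    density = counts / (total * width) if total else counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, density, skipped
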