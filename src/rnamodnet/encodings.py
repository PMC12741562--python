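"""Feature encodings for fixed-length RNA windows.

Twelve schemes used for the conventional-ML benchmark (ANF, binary/one-hot,
CKSNAP, DNC, ENAC, Kmer, NAC, TNC, RCKmer, EIIP, NCP, PseDNC) plus the
series-correlation variant SCPseDNC and the L x 4 one-hot matrix consumed by
the network.  Feature ordering is lexicographic over (A, C, G, U) and
positions run 5'->3' throughout.

Dimensionalities for the default 41-nt window: NAC 4, DNC 16, TNC 64,
Kmer 4^k, CKSNAP 96 (k_max=5), ENAC 148 (win=5), ANF 164, one-hot 164,
NCP 123, EIIP 41, PseDNC 16+lambda, SCPseDNC 16+lambda*6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .seqio import SequenceWindow

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_RC = str.maketrans("ACGU", "UGCA")

#: Electron-ion interaction pseudopotential values for the four bases.
#: Standard published constants, shipped as a configuration default
#: (user-overridable), not derived from any dataset in this package.
EIIP_VALUES: dict[str, float] = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}


class AmbiguousBaseError(ValueError):
    """Raised when an encoding that is undefined over 'N' meets one."""


@dataclass
class FeatureVector:
    scheme: str
    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_names and len(self.feature_names) != len(self.values):
            raise ValueError("feature_names length mismatch")

    def __len__(self):
        return len(self.values)


@dataclass
class EncodedMatrix:
    scheme: str
    values: np.ndarray  # L x C
    column_order: tuple[str, ...] = tuple(BASES)

    def flatten(self) -> FeatureVector:
        L, C = self.values.shape
        names = [f"pos{p + 1}_{c}" for p in range(L) for c in self.column_order]
        return FeatureVector(self.scheme, self.values.reshape(-1), names)


def _seq(window) -> str:
    if isinstance(window, SequenceWindow):
        return window.sequence
    return str(window)


def _check_unambiguous(seq: str, scheme: str):
    if any(b not in _BASE_INDEX for b in seq):
        bad = sorted({b for b in seq if b not in _BASE_INDEX})
        raise AmbiguousBaseError(f"{scheme} undefined over ambiguous bases {bad}")


def _indices(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))


# ---------------------------------------------------------------------------
# matrix encodings
# ---------------------------------------------------------------------------


def one_hot(window) -> EncodedMatrix:
    """L x 4 one-hot matrix, columns (A,C,G,U); 'N' gives an all-zero row."""
    seq = _seq(window)
    m = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        j = _BASE_INDEX.get(b)
        if j is not None:
            m[i, j] = 1.0
    return EncodedMatrix("binary", m)


def ncp(window) -> EncodedMatrix:
    """Nucleotide chemical property: per position (ring, functional group,
    hydrogen bonding) -> A (1,1,1), C (0,1,0), G (1,0,0), U (0,0,1)."""
    seq = _seq(window)
    _check_unambiguous(seq, "ncp")
    table = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}
    m = np.array([table[b] for b in seq], dtype=float)
    return EncodedMatrix("ncp", m, column_order=("purine", "amino", "weak_hbond"))


# ---------------------------------------------------------------------------
# compositional encodings
# ---------------------------------------------------------------------------


def nac(window) -> FeatureVector:
    seq = _seq(window)
    _check_unambiguous(seq, "nac")
    counts = np.bincount(_indices(seq), minlength=4).astype(float)
    return FeatureVector("nac", counts / len(seq), list(BASES))


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    idx = _indices(seq)
    n = len(seq) - k + 1
    codes = np.zeros(n, dtype=np.intp)
    for j in range(k):
        codes = codes * 4 + idx[j : j + n]
    return np.bincount(codes, minlength=4**k).astype(float)


def _kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def dnc(window) -> FeatureVector:
    seq = _seq(window)
    _check_unambiguous(seq, "dnc")
    if len(seq) < 2:
        raise ValueError("dnc needs length >= 2")
    return FeatureVector("dnc", _kmer_counts(seq, 2) / (len(seq) - 1), _kmer_names(2))


def tnc(window) -> FeatureVector:
    seq = _seq(window)
    _check_unambiguous(seq, "tnc")
    if len(seq) < 3:
        raise ValueError("tnc needs length >= 3")
    return FeatureVector("tnc", _kmer_counts(seq, 3) / (len(seq) - 2), _kmer_names(3))


def kmer(window, k: int = 3) -> FeatureVector:
    """Frequencies of the 4^k overlapping k-mers (sum to 1)."""
    seq = _seq(window)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(seq) < k:
        raise ValueError(f"window shorter than k={k}")
    _check_unambiguous(seq, "kmer")
    return FeatureVector(f"kmer{k}", _kmer_counts(seq, k) / (len(seq) - k + 1),
                         _kmer_names(k))


def rckmer(window, k: int = 3) -> FeatureVector:
    """Kmer frequencies collapsed over reverse-complement classes
    (canonical k-mer = lexicographic min of the pair)."""
    seq = _seq(window)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(seq) < k:
        raise ValueError(f"window shorter than k={k}")
    _check_unambiguous(seq, "rckmer")
    counts = _kmer_counts(seq, k)
    names = _kmer_names(k)
    canonical: dict[str, float] = {}
    for name, c in zip(names, counts):
        rc = name.translate(_RC)[::-1]
        canonical[min(name, rc)] = canonical.get(min(name, rc), 0.0) + c
    keys = sorted(canonical)
    vals = np.array([canonical[n] for n in keys])
    return FeatureVector(f"rckmer{k}", vals / (len(seq) - k + 1), keys)


def cksnap(window, k_max: int = 5) -> FeatureVector:
    """Composition of K-spaced nucleic-acid pairs: for each gap K in
    0..k_max, the 16 pair frequencies over the L-K-1 pairs (block sums 1)."""
    seq = _seq(window)
    _check_unambiguous(seq, "cksnap")
    L = len(seq)
    if L <= k_max + 1:
        raise ValueError(f"window too short for k_max={k_max}")
    idx = _indices(seq)
    blocks, names = [], []
    pair_names = _kmer_names(2)
    for K in range(k_max + 1):
        n = L - K - 1
        codes = idx[:n] * 4 + idx[K + 1 :]
        blocks.append(np.bincount(codes, minlength=16).astype(float) / n)
        names.extend(f"{p}.gap{K}" for p in pair_names)
    return FeatureVector("cksnap", np.concatenate(blocks), names)


def enac(window, win: int = 5) -> FeatureVector:
    """Local NAC in each length-``win`` window sliding 5'->3' with stride 1."""
    seq = _seq(window)
    _check_unambiguous(seq, "enac")
    L = len(seq)
    if L < win:
        raise ValueError(f"window shorter than ENAC win={win}")
    onehot = one_hot(seq).values
    csum = np.vstack([np.zeros(4), np.cumsum(onehot, axis=0)])
    local = (csum[win:] - csum[:-win]) / win  # (L-win+1, 4)
    names = [f"win{p + 1}_{b}" for p in range(L - win + 1) for b in BASES]
    return FeatureVector("enac", local.reshape(-1), names)


def anf(window) -> FeatureVector:
    """Accumulated nucleotide frequency: at each position l the 4-vector of
    cumulative (A,C,G,U) frequencies over the prefix 1..l; flattened 4L."""
    seq = _seq(window)
    _check_unambiguous(seq, "anf")
    onehot = one_hot(seq).values
    cum = np.cumsum(onehot, axis=0)
    dens = cum / np.arange(1, len(seq) + 1)[:, None]
    names = [f"pos{p + 1}_{b}" for p in range(len(seq)) for b in BASES]
    return FeatureVector("anf", dens.reshape(-1), names)


def anf_position(window, l: int) -> np.ndarray:
    """The ANF 4-vector at 1-based position ``l`` (prefix composition)."""
    seq = _seq(window)
    return anf(seq).values.reshape(len(seq), 4)[l - 1]


def eiip(window, value_table: Mapping[str, float] | None = None) -> FeatureVector:
    """Per-position electron-ion interaction pseudopotential of the base."""
    seq = _seq(window)
    if len(seq) == 0:
        raise ValueError("empty window")
    table = dict(EIIP_VALUES if value_table is None else value_table)
    missing = sorted({b for b in seq if b not in table})
    if missing:
        raise KeyError(f"EIIP table missing bases {missing}")
    vals = np.array([table[b] for b in seq], dtype=float)
    names = [f"pos{p + 1}" for p in range(len(seq))]
    return FeatureVector("eiip", vals, names)


# ---------------------------------------------------------------------------
# pseudo dinucleotide composition
# ---------------------------------------------------------------------------


def load_property_table(path=None) -> dict[str, np.ndarray]:
    """Dinucleotide -> standardized property vector (6 indices by default:
    rise, roll, shift, slide, tilt, twist)."""
    if path is None:
        src = resources.files("rnamodnet.data") / "rna_dinucleotide_properties.tsv"
        lines = src.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    rows = [ln.split("\t") for ln in lines if ln.strip() and not ln.startswith("#")]
    header, body = rows[0], rows[1:]
    table = {r[0]: np.array([float(x) for x in r[1:]]) for r in body}
    mat = np.array([table[d] for d in sorted(table)])
    mean, std = mat.mean(axis=0), mat.std(axis=0)
    std[std == 0] = 1.0
    return {d: (v - mean) / std for d, v in table.items()}


def _correlation_terms(seq: str, lam: int, props: Mapping[str, np.ndarray]):
    """Per-tier matrices of property vectors C_u at each dinucleotide."""
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    missing = sorted({d for d in dinucs if d not in props})
    if missing:
        raise KeyError(f"property table missing dinucleotides {missing}")
    return np.array([props[d] for d in dinucs])  # (L-1, mu)


def psednc(window, lam: int = 2, w: float = 0.1,
           property_table: Mapping[str, np.ndarray] | None = None) -> FeatureVector:
    """Pseudo dinucleotide composition, length 16 + lambda.

    First 16 entries are the dinucleotide frequencies, the last ``lam`` the
    tier correlations theta_j (mean over tiers of the squared property
    difference averaged over the ``mu`` standardized indices), all sharing
    the denominator sum(f) + w*sum(theta) so the vector sums to 1.
    """
    seq = _seq(window)
    _check_unambiguous(seq, "psednc")
    L = len(seq)
    if not 1 <= lam <= L - 2:
        raise ValueError(f"lambda must be in [1, L-2], got {lam}")
    if not 0 <= w <= 1:
        raise ValueError("w must be in [0, 1]")
    props = load_property_table() if property_table is None else property_table
    C = _correlation_terms(seq, lam, props)  # (L-1, mu)
    f = _kmer_counts(seq, 2) / (L - 1)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = C[:-j] - C[j:]
        thetas[j - 1] = np.mean(np.sum(diff**2, axis=1) / C.shape[1])
    denom = f.sum() + w * thetas.sum()
    vals = np.concatenate([f, w * thetas]) / denom
    names = _kmer_names(2) + [f"theta{j}" for j in range(1, lam + 1)]
    return FeatureVector("psednc", vals, names)


def scpsednc(window, lam: int = 2, w: float = 0.1,
             property_table: Mapping[str, np.ndarray] | None = None) -> FeatureVector:
    """Series-correlation PseDNC, length 16 + lambda*mu: one correlation
    factor per (tier, property) pair instead of the property-averaged
    theta, so mu=1 collapses to PseDNC."""
    seq = _seq(window)
    _check_unambiguous(seq, "scpsednc")
    L = len(seq)
    if not 1 <= lam <= L - 2:
        raise ValueError(f"lambda must be in [1, L-2], got {lam}")
    props = load_property_table() if property_table is None else property_table
    C = _correlation_terms(seq, lam, props)
    mu = C.shape[1]
    f = _kmer_counts(seq, 2) / (L - 1)
    taus = np.empty(lam * mu)
    for j in range(1, lam + 1):
        diff = (C[:-j] - C[j:]) ** 2
        taus[(j - 1) * mu : j * mu] = diff.mean(axis=0)
    denom = f.sum() + w * taus.sum()
    vals = np.concatenate([f, w * taus]) / denom
    names = _kmer_names(2) + [
        f"tau{j}_p{u + 1}" for j in range(1, lam + 1) for u in range(mu)
    ]
    return FeatureVector("scpsednc", vals, names)


# ---------------------------------------------------------------------------
# registry / dispatch
# ---------------------------------------------------------------------------

#: the 12 benchmark schemes, in the conventional order
SCHEMES = {
    "anf": anf,
    "binary": lambda w, **kw: one_hot(w).flatten(),
    "cksnap": cksnap,
    "dnc": dnc,
    "eiip": eiip,
    "enac": enac,
    "kmer": kmer,
    "nac": nac,
    "ncp": lambda w, **kw: ncp(w).flatten(),
    "psednc": psednc,
    "rckmer": rckmer,
    "tnc": tnc,
}

_EXTRA = {
    "scpsednc": scpsednc,
    "onehot_matrix": lambda w, **kw: one_hot(w),
    "ncp_matrix": lambda w, **kw: ncp(w),
}


def encode(window, scheme: str, **params):
    """Dispatch to a registered scheme; unknown names raise with the list
    of registered schemes."""
    fn = SCHEMES.get(scheme) or _EXTRA.get(scheme)
    if fn is None:
        known = sorted(set(SCHEMES) | set(_EXTRA))
        raise KeyError(f"unknown encoding {scheme!r}; registered: {known}")
    return fn(window, **params)


def encode_many(windows, scheme: str, **params) -> np.ndarray:
    """Stack an encoding over windows into an (n, d) feature matrix
    (matrix schemes are flattened)."""
    rows = []
    for w in windows:
        enc = encode(w, scheme, **params)
        if isinstance(enc, EncodedMatrix):
            enc = enc.flatten()
        rows.append(enc.values)
    return np.asarray(rows)
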