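"""Fixed-length sequence encodings for PPI prediction.

Four techniques map an amino-acid sequence to a numeric vector of fixed
length, independent of sequence length:

* AC — autocovariance of seven physicochemical property profiles at lags
  1..lg (default 30): 210 values.
* CT — conjoint triad: frequencies of the 343 = 7^3 consecutive group
  triples over the seven-group alphabet.
* LD — local descriptor: composition / transition / distribution statistics
  (63 values) over ten overlapping sequence regions: 630 values.
* PseAAC — pseudo-amino-acid composition: the 20 residue frequencies plus
  lambda weighted sequence-order correlation terms: 20 + lambda values.

All four operate on the raw sequence string and are pure functions: the same
input always produces bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .properties import (
    AMBIGUOUS_GROUP,
    SEVEN_GROUPS,
    PropertyTable,
    ac_property_table,
    pseaac_property_table,
)
from .records import STANDARD_AA

TECHNIQUES = ("ac", "ct", "ld", "pseaac")

# ---------------------------------------------------------------------------
# autocovariance


def ac_encode(
    seq: str,
    props: PropertyTable | None = None,
    lg: int = 30,
    policy: str = "impute",
) -> np.ndarray:
    """Autocovariance encoding: lg lags x 7 properties = 210 values.

    Entry (lag, j) is the lag-autocovariance of property j's per-residue
    profile: the mean over i of (X[i,j] - mean_j) * (X[i+lag,j] - mean_j)
    with mean_j taken over the whole sequence and the sum over i divided by
    L - lag.  Ordering is lag-major: all 7 properties for lag 1, then lag 2,
    and so on.
    """
    if props is None:
        props = ac_property_table()
    L = len(seq)
    if L <= lg:
        raise ValueError(
            f"sequence length {L} must exceed the maximum lag {lg} "
            f"(minimum length {lg + 1})"
        )
    X = props.profile(seq, policy=policy)  # (L, p)
    Xc = X - X.mean(axis=0)
    p = X.shape[1]
    out = np.empty((lg, p), dtype=float)
    for lag in range(1, lg + 1):
        out[lag - 1] = (Xc[: L - lag] * Xc[lag:]).sum(axis=0) / (L - lag)
    return out.ravel()


def ac_feature_names(props: PropertyTable | None = None, lg: int = 30) -> list[str]:
    names = (props or ac_property_table()).names
    return [f"AC_lag{lag:02d}_{n}" for lag in range(1, lg + 1) for n in names]


# ---------------------------------------------------------------------------
# conjoint triad


def ct_group(seq: str, gmap: dict[str, int] | None = None, policy: str = "impute") -> str:
    """Map a sequence to its string of group digits 1-7.

    Under the "impute" policy, ambiguity codes with a dominant resolution
    (B, Z, U) take that group; residues with none (X, J, O) are dropped with
    a warning.  Under "strict", any non-standard residue raises, naming its
    position.
    """
    gmap = gmap or SEVEN_GROUPS
    digits = []
    for i, aa in enumerate(seq):
        g = gmap.get(aa)
        if g is None:
            if policy == "strict":
                raise ValueError(f"unmappable residue {aa!r} at position {i + 1}")
            g = AMBIGUOUS_GROUP.get(aa)
            if g is None:
                warnings.warn(
                    f"dropping unmappable residue {aa!r} at position {i + 1}",
                    stacklevel=2,
                )
                continue
        digits.append(str(g))
    return "".join(digits)


def ct_index(g1: int, g2: int, g3: int) -> int:
    """Position of triad (g1, g2, g3) in the 343-vector, lexicographic."""
    return (g1 - 1) * 49 + (g2 - 1) * 7 + (g3 - 1)


def ct_encode(seq: str, gmap: dict[str, int] | None = None, policy: str = "impute") -> np.ndarray:
    """Conjoint-triad frequencies: counts of the L-2 sliding windows / (L-2).

    Only full triads inside the sequence are counted; there is no bin for
    boundary pseudo-triads, so they are omitted.
    """
    grouped = ct_group(seq, gmap, policy)
    L = len(grouped)
    if L < 3:
        raise ValueError(f"need at least 3 groupable residues, got {L}")
    vec = np.zeros(343, dtype=float)
    for i in range(L - 2):
        g1, g2, g3 = (int(grouped[i + k]) for k in range(3))
        vec[ct_index(g1, g2, g3)] += 1.0
    return vec / (L - 2)


def ct_feature_names() -> list[str]:
    return [
        f"CT_{g1}{g2}{g3}"
        for g1 in range(1, 8)
        for g2 in range(1, 8)
        for g3 in range(1, 8)
    ]


# ---------------------------------------------------------------------------
# local descriptor

LD_REGION_NAMES = "ABCDEFGHIJ"

# All 21 unordered pairs of the seven groups, lexicographic; the transition
# descriptor scores each of them, so a region yields 7 + 21 + 35 = 63 values.
LD_TRANSITION_PAIRS = tuple(
    (a, b) for a in range(1, 8) for b in range(a + 1, 8)
)


def ld_regions(seq: str) -> list[str]:
    """Split a sequence into the ten overlapping local-descriptor regions.

    A-D: four quarters (floor-based cut points; their concatenation is the
    sequence).  E-F: the two halves.  G: central 50%.  H: first 75%.
    I: final 75%.  J: central 75%.
    """
    L = len(seq)
    if L < 8:
        raise ValueError(f"sequence length {L} < 8: some regions would be empty")
    q1, q2, q3 = (L * k // 4 for k in (1, 2, 3))
    half = L // 2
    e8, l8 = L // 8, 7 * L // 8
    return [
        seq[:q1],
        seq[q1:q2],
        seq[q2:q3],
        seq[q3:],
        seq[:half],
        seq[half:],
        seq[q1:q3],          # central 50%
        seq[:q3],            # first 75%
        seq[L - q3:],        # final 75%
        seq[e8:l8],          # central 75%
    ]


def ld_ctd(
    subseq: str,
    gmap: dict[str, int] | None = None,
    policy: str = "impute",
    distribution: str = "paper",
) -> np.ndarray:
    """Composition/transition/distribution statistics of one region: 63 values.

    C (7): fraction of residues in each group.
    T (21): frequency of each unordered group pair among the n-1 adjacent
    position pairs, counted regardless of direction.
    D (35): for each group with count c > 0, five quantile statistics.  The
    default "paper" form is count-index based: 1/n, then
    floor(q*c + 0.5)/n for q in {0.25, 0.5, 0.75, 1.0}.  The "positional"
    alternative reports the 1-based sequence position of the residue at each
    quantile of the group's occurrences, divided by n.
    """
    grouped = ct_group(subseq, gmap, policy)
    n = len(grouped)
    if n < 2:
        raise ValueError(f"region needs at least 2 groupable residues, got {n}")
    gs = np.frombuffer(grouped.encode(), dtype=np.uint8) - ord("0")

    comp = np.bincount(gs, minlength=8)[1:8] / n

    trans = np.zeros(len(LD_TRANSITION_PAIRS), dtype=float)
    pair_idx = {frozenset(p): i for i, p in enumerate(LD_TRANSITION_PAIRS)}
    for a, b in zip(gs[:-1], gs[1:]):
        if a != b:
            i = pair_idx.get(frozenset((int(a), int(b))))
            if i is not None:
                trans[i] += 1.0
    trans /= n - 1

    dist = np.zeros((7, 5), dtype=float)
    for g in range(1, 8):
        positions = np.flatnonzero(gs == g)  # 0-based
        c = len(positions)
        if c == 0:
            continue
        if distribution == "paper":
            dist[g - 1, 0] = 1.0 / n
            for k, q in enumerate((0.25, 0.5, 0.75, 1.0), start=1):
                dist[g - 1, k] = math.floor(q * c + 0.5) / n
        elif distribution == "positional":
            for k, q in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
                j = 0 if q == 0.0 else math.ceil(q * c) - 1
                dist[g - 1, k] = (positions[j] + 1) / n
        else:
            raise ValueError(f"unknown distribution variant {distribution!r}")

    return np.concatenate([comp, trans, dist.ravel()])


def ld_encode(
    seq: str,
    gmap: dict[str, int] | None = None,
    policy: str = "impute",
    distribution: str = "paper",
) -> np.ndarray:
    """Local-descriptor encoding: 10 regions x 63 statistics = 630 values."""
    return np.concatenate(
        [ld_ctd(r, gmap, policy, distribution) for r in ld_regions(seq)]
    )


def ld_feature_names() -> list[str]:
    names = []
    for region in LD_REGION_NAMES:
        names += [f"LD_{region}_C{g}" for g in range(1, 8)]
        names += [f"LD_{region}_T{a}{b}" for a, b in LD_TRANSITION_PAIRS]
        names += [
            f"LD_{region}_D{g}_q{q}"
            for g in range(1, 8)
            for q in (0, 25, 50, 75, 100)
        ]
    return names


# ---------------------------------------------------------------------------
# pseudo-amino-acid composition


@dataclass
class PseAACParams:
    """Parameters of the PseAAC encoding.

    lambda_ is the sequence-order depth (number of correlation tiers); omega
    weights the correlation terms against the plain composition.  The three
    properties are hydrophobicity, hydrophilicity and side-chain mass,
    standardized over the 20 amino acids.  correlation="paper" uses the plain
    property difference H_p(A_{i+j}) - H_p(A_i) as the order-relationship
    term; "squared" uses the squared difference of canonical PseAAC.
    """

    lambda_: int = 15
    omega: float = 0.05
    correlation: str = "paper"
    props: PropertyTable = field(default_factory=pseaac_property_table)

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.correlation not in ("paper", "squared"):
            raise ValueError(f"unknown correlation variant {self.correlation!r}")


def pseaac_encode(seq: str, params: PseAACParams | None = None, policy: str = "impute") -> np.ndarray:
    """PseAAC encoding: 20 composition terms plus lambda order terms.

    The composition terms are the residue frequencies f_k; the order terms
    are omega * theta_j where theta_j averages the pairwise order
    relationship of residues j apart; the whole vector is divided by
    sum(f) + omega * sum(theta), so its entries sum to 1.
    """
    params = params or PseAACParams()
    L = len(seq)
    lam = params.lambda_
    if lam >= L:
        raise ValueError(f"lambda={lam} must be < sequence length {L}")

    counts = np.zeros(20, dtype=float)
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    n_std = 0
    for i, aa in enumerate(seq):
        j = index.get(aa)
        if j is None and policy == "strict":
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        if j is not None:
            counts[j] += 1
            n_std += 1
    if n_std == 0:
        raise ValueError("sequence has no standard residues")
    freqs = counts / n_std

    H = params.props.profile(seq, policy=policy)  # (L, 3)
    theta = np.zeros(lam, dtype=float)
    for j in range(1, lam + 1):
        diff = H[j:] - H[:-j]
        if params.correlation == "squared":
            corr = (diff**2).mean(axis=1)
        else:
            corr = diff.mean(axis=1)
        theta[j - 1] = corr.sum() / (L - j)

    denom = freqs.sum() + params.omega * theta.sum()
    if denom == 0:
        raise ValueError("degenerate normalization: sum(f) + omega*sum(theta) == 0")
    return np.concatenate([freqs, params.omega * theta]) / denom


def pseaac_feature_names(lambda_: int = 15) -> list[str]:
    return [f"PseAAC_f_{aa}" for aa in STANDARD_AA] + [
        f"PseAAC_theta_{j:02d}" for j in range(1, lambda_ + 1)
    ]


# ---------------------------------------------------------------------------
# dispatch


def encode(seq: str, technique: str, **kwargs) -> np.ndarray:
    """Encode a sequence under one technique name ("ac"/"ct"/"ld"/"pseaac")."""
    technique = technique.lower()
    if technique == "ac":
        return ac_encode(seq, **kwargs)
    if technique == "ct":
        return ct_encode(seq, **kwargs)
    if technique == "ld":
        return ld_encode(seq, **kwargs)
    if technique == "pseaac":
        return pseaac_encode(seq, **kwargs)
    raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")


def encoding_length(technique: str, lg: int = 30, lambda_: int = 15) -> int:
    return {"ac": lg * 7, "ct": 343, "ld": 630, "pseaac": 20 + lambda_}[
        technique.lower()
    ]


def feature_names(technique: str, lg: int = 30, lambda_: int = 15) -> list[str]:
    technique = technique.lower()
    if technique == "ac":
        return ac_feature_names(lg=lg)
    if technique == "ct":
        return ct_feature_names()
    if technique == "ld":
        return ld_feature_names()
    if technique == "pseaac":
        return pseaac_feature_names(lambda_)
    raise ValueError(f"unknown technique {technique!r}")


def encode_collection(records, technique: str, **kwargs) -> dict[str, np.ndarray]:
    """Encode every record of a collection; returns id -> feature vector."""
    return {rec.id: encode(rec.seq, technique, **kwargs) for rec in records}
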