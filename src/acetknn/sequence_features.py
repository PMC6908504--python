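"""Sequence-intrinsic feature encoders.

Two encoders live here:

* type-1 pseudo amino acid composition (PseAAC): 20 damped residue
  frequencies plus ``lam`` sequence-order correlation factors computed from
  standardized hydrophobicity, hydrophilicity and side-chain mass tables;
* a GM(1,1) grey-model summary of each PSSM column, capturing the trend of
  evolutionary conservation along the sequence in 80 numbers
  (developing coefficient a, grey input b, mean, SD per residue column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import AMINO_ACIDS

logger = logging.getLogger(__name__)

# Physicochemical property tables indexed by residue, in the order of
# dataio.AMINO_ACIDS. Values are the canonical type-1 PseAAC triple:
# hydrophobicity, hydrophilicity, side-chain mass.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardize(table: dict) -> np.ndarray:
    """Zero-mean, unit (population) SD over the 20 residues."""
    v = np.array([table[aa] for aa in AMINO_ACIDS])
    return (v - v.mean()) / v.std()


@dataclass
class PseaacParams:
    """Parameters of the type-1 PseAAC encoding.

    lam is the sequence-order correlation depth (lambda; default 5, giving a
    25-component vector), weight the damping factor w (default 0.05). The
    three property tables are stored standardized to mean 0 / SD 1 over the
    20 residues, as the type-1 definition requires.
    """

    lam: int = 5
    weight: float = 0.05
    properties: np.ndarray = field(
        default_factory=lambda: np.vstack(
            [
                _standardize(_HYDROPHOBICITY),
                _standardize(_HYDROPHILICITY),
                _standardize(_SIDECHAIN_MASS),
            ]
        )
    )

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def n_features(self) -> int:
        return 20 + self.lam


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_pseaac(sequence: str, params: PseaacParams | None = None) -> np.ndarray:
    """Encode a canonical sequence as a (20 + lam)-vector summing to 1.

    Components 1..20 are residue frequencies damped by the correlation
    terms; components 21..20+lam are the tier correlations theta_j, each the
    average over positions of Theta(R_i, R_{i+j}) — the mean squared
    difference of the three standardized properties between residues j
    apart. The full vector is normalized so its components sum to 1.
    """
    params = params or PseaacParams()
    L = len(sequence)
    if L <= params.lam:
        raise ValueError(
            f"sequence length {L} must exceed lambda={params.lam}; "
            "drop or pad the sequence"
        )
    idx = np.array([_AA_INDEX[aa] for aa in sequence])
    freqs = np.bincount(idx, minlength=20) / L
    props = params.properties[:, idx]  # 3 x L
    thetas = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        diffs = props[:, j:] - props[:, :-j]  # 3 x (L - j)
        thetas[j - 1] = np.mean(diffs**2)
    w = params.weight
    denom = 1.0 + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


def pseaac_feature_names(params: PseaacParams | None = None) -> list:
    params = params or PseaacParams()
    return [f"pseaac_f_{aa}" for aa in AMINO_ACIDS] + [
        f"pseaac_theta_{j}" for j in range(1, params.lam + 1)
    ]


def gm11_fit(series: np.ndarray) -> tuple[float, float]:
    """Fit the GM(1,1) grey model to a series of length >= 4.

    Forms the accumulated series x1 = cumsum(x0) and background values
    z1(k) = (x1(k) + x1(k-1)) / 2, then solves x0(k) + a*z1(k) = b for
    k = 2..n by least squares. Returns the developing coefficient ``a`` and
    grey input ``b``. If all background values coincide (e.g. the all-zero
    series) the normal equations are singular and the documented fallback
    (a = 0, b = mean(x0)) applies.
    """
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or x0.size < 4:
        raise ValueError("GM(1,1) needs a 1-D series of length >= 4")
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    if np.ptp(z1) < 1e-12:
        logger.info("GM(1,1): degenerate background series; returning (0, mean)")
        return 0.0, float(x0.mean())
    design = np.column_stack([-z1, np.ones_like(z1)])
    coef, *_ = np.linalg.lstsq(design, x0[1:], rcond=None)
    return float(coef[0]), float(coef[1])


def logistic_rescale(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def minmax_rescale(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    span = np.ptp(x)
    if span == 0:
        return np.full_like(x, 0.5)
    return (x - x.min()) / span


_RESCALERS = {"logistic": logistic_rescale, "minmax": minmax_rescale}


def encode_gray_pssm(pssm: np.ndarray, rescale: str = "logistic") -> np.ndarray:
    """Summarize an L x 20 PSSM as 80 grey-model features.

    Each column (fixed PSI-BLAST residue order) is rescaled into (0, 1) —
    GM(1,1) assumes a positive series, while log-odds are signed — and
    summarized by the quadruple (a, b, mean, sd). Output is column-major:
    (a, b, mean, sd) for column 1, then column 2, ... 20 x 4 = 80 values.
    """
    pssm = np.asarray(pssm, dtype=float)
    if pssm.ndim != 2 or pssm.shape[1] != 20:
        raise ValueError(f"PSSM must be L x 20, got {pssm.shape}")
    if pssm.shape[0] < 4:
        raise ValueError("PSSM needs at least 4 rows for GM(1,1)")
    try:
        rescaler = _RESCALERS[rescale]
    except KeyError:
        raise ValueError(f"rescale must be one of {sorted(_RESCALERS)}") from None
    out = np.empty(80)
    for c in range(20):
        u = rescaler(pssm[:, c])
        a, b = gm11_fit(u)
        out[4 * c : 4 * c + 4] = (a, b, u.mean(), u.std())
    return out


def gray_pssm_feature_names() -> list:
    from .dataio import PSSM_AA_ORDER

    names = []
    for aa in PSSM_AA_ORDER:
        names += [f"gray_{aa}_{part}" for part in ("a", "b", "mean", "sd")]
    return names
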