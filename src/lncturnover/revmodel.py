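"""General time-reversible (REV/GTR) nucleotide substitution model.

The rate matrix is Q_ij = s_ij * pi_j for i != j, with symmetric
exchangeabilities s and stationary frequencies pi, scaled so that the
expected number of substitutions per site per unit branch length is one
(-sum_i pi_i Q_ii = 1). Distances d are therefore in substitutions/site.

Bases are ordered A, C, G, T throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

# order of the six exchangeability parameters
PAIR_ORDER = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


@dataclass(frozen=True)
class RevParams:
    """Exchangeabilities (length-6, order AC, AG, AT, CG, CT, GT) and
    stationary frequencies (length-4, order ACGT)."""

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    frequencies: tuple[float, ...] = (0.25,) * 4

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (6,) or np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("exchangeabilities must be 6 non-negative finite numbers")
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be 4 non-negative numbers summing to 1")

    @property
    def s_matrix(self) -> np.ndarray:
        S = np.zeros((4, 4))
        for (a, b), v in zip(PAIR_ORDER, self.exchangeabilities):
            i, j = BASE_INDEX[a], BASE_INDEX[b]
            S[i, j] = S[j, i] = v
        return S

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


JC_PARAMS = RevParams()


def rate_matrix(params: RevParams) -> np.ndarray:
    """Scaled GTR rate matrix (expected rate 1 substitution/site/unit d).

    Returns the zero matrix when the composition admits no substitutions
    (e.g. a single-base alphabet), in which case P(d) = I for all d.
    """
    S = params.s_matrix
    pi = params.pi
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        return np.zeros((4, 4))
    return Q / mu


def transition_probabilities(params: RevParams, d: float) -> np.ndarray:
    """P(d) = exp(Q d), computed via the symmetric eigendecomposition
    B = D^{1/2} Q D^{-1/2} with D = diag(pi)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    Q = rate_matrix(params)
    if not Q.any() or d == 0:
        return np.eye(4)
    pi = np.clip(params.pi, 1e-12, None)
    sqrt_pi = np.sqrt(pi)
    B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    P = (U * np.exp(w * d)) @ U.T
    P = P / sqrt_pi[:, None] * sqrt_pi[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes; other characters become -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASE_ORDER[c] for c in codes)


def pair_count_matrix(seq1: str, seq2: str) -> tuple[np.ndarray, int]:
    """4x4 site-pattern count matrix N[i, j] = #{sites with (seq1=i, seq2=j)}.

    Columns containing non-ACGT characters in either sequence are dropped;
    the number of dropped columns is returned alongside.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    a = encode(seq1)
    b = encode(seq2)
    keep = (a >= 0) & (b >= 0)
    dropped = int((~keep).sum())
    a = a[keep].astype(np.int64)
    b = b[keep].astype(np.int64)
    N = np.bincount(4 * a + b, minlength=16).reshape(4, 4).astype(float)
    return N, dropped


def jc_distance(p: float) -> float:
    """Jukes-Cantor closed form for an observed proportion p of differing
    sites."""
    if p < 0 or p >= 0.75:
        raise ValueError("p must be in [0, 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)
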