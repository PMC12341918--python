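"""Genomic covariance structures for the 2x-4x triploid cross model.

Builds the ploidy-general additive GRMs of the diploid (``AD``) and
tetraploid (``AT``) parental populations, the dominance regressor and its
expectation over a cross's progeny under polysomic tetraploid inheritance,
the expected inbreeding coefficient ``F`` and expected dominance GRM ``D``
between crosses, and the across-population additive-by-additive epistasis
matrix (a principal submatrix of the Kronecker product ``AD x AT``).

All cross-level quantities use the hybrid ploidy P = 3 in the regressor
constants tau_P, xi_P and in the binomial coefficient C(P, 2); parental
ploidies enter only through allele dosages.  Tetraploid parents are
colchicine-doubled diploids, so their dosage is twice the diploid base.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .genotypes import ParentGenotypes

PSD_TOL = 1e-8  # eigenvalue tolerance when checking positive semidefiniteness
HYBRID_PLOIDY = 3

# Denominator conventions (reduce to the standard diploid dominance
# normalisations at P = 2: 2*sum f(1-f) and sum (2f(1-f))^2):
#   F uses  C(P,2) * 2 * sum_m f(1-f)
#   D uses  C(P,2)^2 * 4 * sum_m f^2 (1-f)^2
F_DENOM_FACTOR = comb(HYBRID_PLOIDY, 2) * 2
D_DENOM_FACTOR = comb(HYBRID_PLOIDY, 2) ** 2 * 4


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValueError(
            "allele frequencies must lie strictly in (0, 1); filter "
            "monomorphic markers upstream"
        )
    return freqs


def additive_grm(dosages: np.ndarray, ploidy: int, freqs: np.ndarray) -> np.ndarray:
    """Ploidy-general additive genomic relationship matrix.

    ``A_ij = sum_m (X_im - P f_m)(X_jm - P f_m) / (P sum_m f_m (1 - f_m))``.

    For doubled-diploid tetraploids (dosage exactly twice the diploid base,
    same frequencies) this yields ``A4 = 2 * A2`` entrywise.
    """
    freqs = _check_freqs(freqs)
    dosages = np.asarray(dosages, dtype=float)
    if dosages.min() < 0 or dosages.max() > ploidy:
        raise ValueError(f"dosages out of range [0, {ploidy}]")
    centered = dosages - ploidy * freqs
    denom = ploidy * np.sum(freqs * (1.0 - freqs))
    A = (centered @ centered.T) / denom
    return (A + A.T) / 2.0


def regressor_constants(ploidy: int, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """``tau_P = (P-1) f (1-f) + 1/4`` and ``xi_P = (P-1) f + 1/2``."""
    freqs = np.asarray(freqs, dtype=float)
    tau = (ploidy - 1) * freqs * (1.0 - freqs) + 0.25
    xi = (ploidy - 1) * freqs + 0.5
    return tau, xi


def dominance_regressor(dosage, ploidy: int, freq) -> np.ndarray:
    """Dominance regressor ``Q = tau_P - (X - xi_P)^2`` for an individual.

    Its expectation is zero over Hardy-Weinberg genotype frequencies.
    """
    dosage = np.asarray(dosage, dtype=float)
    if np.any((dosage < 0) | (dosage > ploidy)):
        raise ValueError(f"dosage out of range [0, {ploidy}]")
    tau, xi = regressor_constants(ploidy, np.asarray(freq, dtype=float))
    return tau - (dosage - xi) ** 2


def expected_hybrid_regressor(x2, x4, freq):
    """Expected triploid dominance regressor of a 2x-4x cross at one marker.

    ``x2`` is the diploid parent's dosage (0..2), ``x4`` the tetraploid
    parent's dosage (0..4).  The hybrid dosage X is one Mendelian 2x gamete
    plus one polysomic 4x gamete (random bivalent pairing), giving the exact
    moments::

        E(X)   = (x2 + x4) / 2
        E(X^2) = x2/2 + (2 x4 + x4^2)/6 + x2 x4 / 2

    and ``Q_uv = tau_3 - xi_3^2 - E(X^2) + E(X) (4 f + 1)``.

    Returns ``(Q_uv, E(X), E(X^2))`` as arrays broadcast over the inputs.
    """
    x2 = np.asarray(x2, dtype=float)
    x4 = np.asarray(x4, dtype=float)
    freq = _check_freqs(np.asarray(freq, dtype=float))
    if np.any((x2 < 0) | (x2 > 2)):
        raise ValueError("2x parent dosage out of range [0, 2]")
    if np.any((x4 < 0) | (x4 > 4)):
        raise ValueError("4x parent dosage out of range [0, 4]")
    ex = (x2 + x4) / 2.0
    ex2 = x2 / 2.0 + (2.0 * x4 + x4**2) / 6.0 + x2 * x4 / 2.0
    tau, xi = regressor_constants(HYBRID_PLOIDY, freq)
    q = tau - xi**2 - ex2 + ex * (4.0 * freq + 1.0)
    return q, ex, ex2


def _cross_regressors(
    crosses: Sequence[tuple[str, str]], geno: ParentGenotypes, freqs: np.ndarray
) -> np.ndarray:
    """(n_crosses, n_markers) matrix of expected hybrid regressors Q_uvm.

    Tetraploid parents are doubled diploids: their dosage is 2x the stored
    diploid base genotype.
    """
    if not crosses:
        raise ValueError("no crosses supplied")
    p2 = geno.index_of([u for u, _ in crosses])
    p4 = geno.index_of([v for _, v in crosses])
    x2 = geno.dosages[p2].astype(float)
    x4 = 2.0 * geno.dosages[p4].astype(float)
    q, _, _ = expected_hybrid_regressor(x2, x4, freqs[None, :])
    return q


def expected_inbreeding(
    crosses: Sequence[tuple[str, str]],
    geno: ParentGenotypes,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Expected genomic inbreeding coefficient per cross.

    ``F_uv = -sum_m Q_uvm / (C(3,2) * 2 * sum_m f (1-f))``.  A cross fixed
    for one allele at every marker gives F = 1; a cross whose progeny match
    Hardy-Weinberg frequencies at every marker gives F = 0.
    """
    freqs = _check_freqs(geno.freqs if freqs is None else freqs)
    if geno.n_markers == 0:
        raise ValueError("empty marker set")
    q = _cross_regressors(crosses, geno, freqs)
    denom = F_DENOM_FACTOR * np.sum(freqs * (1.0 - freqs))
    return -q.sum(axis=1) / denom


def expected_dominance_grm(
    crosses: Sequence[tuple[str, str]],
    geno: ParentGenotypes,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Expected dominance genomic relationship matrix between crosses.

    ``D_{uv,u'v'} = sum_m Q_uvm Q_u'v'm / (C(3,2)^2 * 4 * sum_m f^2 (1-f)^2)``.
    """
    freqs = _check_freqs(geno.freqs if freqs is None else freqs)
    if geno.n_markers == 0:
        raise ValueError("empty marker set")
    q = _cross_regressors(crosses, geno, freqs)
    denom = D_DENOM_FACTOR * np.sum((freqs * (1.0 - freqs)) ** 2)
    D = (q @ q.T) / denom
    return (D + D.T) / 2.0


def epistasis_grm(
    AD: np.ndarray,
    AT: np.ndarray,
    crosses: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Across-population epistasis covariance between crosses.

    ``K_(u,v),(u',v') = AD[u, u'] * AT[v, v']`` for crosses given as index
    pairs into ``AD`` (2x parents) and ``AT`` (4x parents): the principal
    submatrix of the Kronecker product ``AD (x) AT`` at the realized and
    target crosses, hence positive semidefinite.
    """
    iu = np.array([u for u, _ in crosses], dtype=int)
    iv = np.array([v for _, v in crosses], dtype=int)
    if iu.size == 0:
        raise ValueError("no crosses supplied")
    if iu.max() >= AD.shape[0] or iv.max() >= AT.shape[0]:
        raise IndexError("cross parent index outside AD/AT")
    return AD[np.ix_(iu, iu)] * AT[np.ix_(iv, iv)]


def check_psd(mat: np.ndarray, tol: float = PSD_TOL, name: str = "matrix") -> None:
    """Raise if the smallest eigenvalue is below ``-tol`` (no projection)."""
    w = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    if w.min() < -tol:
        raise ValueError(f"{name} is not PSD (min eigenvalue {w.min():.3e})")


@dataclass
class KinshipSet:
    """All covariance structures of the genomic 2x-4x model for one design.

    ``parents2x``/``parents4x`` index ``AD``/``AT``; ``crosses`` (list of
    (2x id, 4x id) pairs) index ``F``, ``Dmat`` and ``Kepi``.
    """

    parents2x: list[str]
    parents4x: list[str]
    crosses: list[tuple[str, str]]
    AD: np.ndarray
    AT: np.ndarray
    F: np.ndarray
    Dmat: np.ndarray
    Kepi: np.ndarray
    n_markers: int
    freqs: np.ndarray

    def cross_index(self, cross: tuple[str, str]) -> int:
        return self.crosses.index((cross[0], cross[1]))


def build_kinship_set(
    geno: ParentGenotypes,
    crosses: Sequence[tuple[str, str]],
    freqs: np.ndarray | None = None,
    jitter: float = 0.0,
    validate: bool = True,
) -> KinshipSet:
    """Assemble AD, AT, F, D and the epistasis matrix for a crossing design.

    Parents used both as 2x and 4x appear as distinct levels of ``AD`` and
    ``AT`` backed by the same diploid base genotype.  An optional ``jitter``
    is added to GRM diagonals for near-singular fits (default off).
    """
    freqs = _check_freqs(geno.freqs if freqs is None else np.asarray(freqs))
    crosses = [(str(u), str(v)) for u, v in crosses]
    parents2x = sorted({u for u, _ in crosses})
    parents4x = sorted({v for _, v in crosses})

    d2 = geno.dosages[geno.index_of(parents2x)].astype(float)
    d4 = 2.0 * geno.dosages[geno.index_of(parents4x)].astype(float)
    AD = additive_grm(d2, 2, freqs)
    AT = additive_grm(d4, 4, freqs)
    if jitter:
        AD = AD + jitter * np.eye(len(parents2x))
        AT = AT + jitter * np.eye(len(parents4x))

    F = expected_inbreeding(crosses, geno, freqs)
    Dmat = expected_dominance_grm(crosses, geno, freqs)
    i2 = {p: i for i, p in enumerate(parents2x)}
    i4 = {p: i for i, p in enumerate(parents4x)}
    Kepi = epistasis_grm(AD, AT, [(i2[u], i4[v]) for u, v in crosses])

    if validate:
        check_psd(AD, name="AD")
        check_psd(AT, name="AT")
        check_psd(Kepi, name="epistasis matrix")
    return KinshipSet(
        parents2x=parents2x,
        parents4x=parents4x,
        crosses=crosses,
        AD=AD,
        AT=AT,
        F=F,
        Dmat=Dmat,
        Kepi=Kepi,
        n_markers=geno.n_markers,
        freqs=freqs,
    )


def save_matrix(mat: np.ndarray, ids: Sequence[str], path: str) -> None:
    """Persist a square matrix as plain text with an identifier header."""
    import pandas as pd

    pd.DataFrame(mat, index=list(ids), columns=list(ids)).to_csv(path)


def load_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
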