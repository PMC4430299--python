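"""Marker-QTL haplotype and genotype algebra.

One biallelic SNP marker (alleles ``M``/``m``) is linked, through linkage
disequilibrium, to a three-allele QTL whose alleles are ``Q``, ``q`` and the
methylated epiallele ``q+``.  In a random-mating (Hardy-Weinberg) population
the two loci form six haplotypes; random union of haplotypes produces 21
unordered diplotypes collapsing to 18 observable two-locus genotypes
(3 marker x 6 QTL classes).

Index conventions used package-wide
-----------------------------------
QTL genotype ``j``:  5=QQ, 4=Qq, 3=Qq+, 2=qq, 1=qq+, 0=q+q+.
Marker genotype ``m``: 2=MM, 1=Mm, 0=mm.
Haplotype order: MQ, Mq, Mq+, mQ, mq, mq+.

Tables returned by this module are indexed ``[m, j]`` with the codes above
(row 0 is therefore ``mm`` and column 5 is ``QQ``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateMarkerError,
    InvalidDisequilibriumError,
    InvalidParameterError,
    UndefinedPhaseError,
)

#: QTL genotype names by index j.
QTL_GENOTYPES = {5: "QQ", 4: "Qq", 3: "Qq+", 2: "qq", 1: "qq+", 0: "q+q+"}
#: Marker genotype names by index m.
MARKER_GENOTYPES = {2: "MM", 1: "Mm", 0: "mm"}
#: Haplotype names in canonical order.
HAPLOTYPES = ("MQ", "Mq", "Mq+", "mQ", "mq", "mq+")

# QTL genotype index from an unordered pair of QTL-allele indices
# (0=Q, 1=q, 2=q+).
_QTL_PAIR_TO_J = {
    frozenset({0}): 5,          # QQ
    frozenset({0, 1}): 4,       # Qq
    frozenset({0, 2}): 3,       # Qq+
    frozenset({1}): 2,          # qq
    frozenset({1, 2}): 1,       # qq+
    frozenset({2}): 0,          # q+q+
}


#: QTL genotype index j -> (allele index, allele index), alleles 0=Q, 1=q, 2=q+.
J_TO_ALLELE_PAIR = {5: (0, 0), 4: (0, 1), 3: (0, 2), 2: (1, 1), 1: (1, 2), 0: (2, 2)}


def qtl_pair_to_index(a: int, b: int) -> int:
    """QTL genotype index j for an unordered pair of allele indices."""
    return _QTL_PAIR_TO_J[frozenset({a, b})]


@dataclass(frozen=True)
class GeneticParams:
    """Population-level genetic parameters.

    Parameters
    ----------
    p_M : frequency of marker allele M.
    q_Q, q_q : frequencies of QTL alleles Q and q; the methylated allele
        q+ has frequency ``1 - q_Q - q_q``.
    d1, d2 : linkage disequilibria coupling M with Q and with q.
    """

    p_M: float
    q_Q: float
    q_q: float
    d1: float
    d2: float

    def __post_init__(self):
        for name in ("p_M", "q_Q", "q_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.q_Q + self.q_q > 1.0 + 1e-12:
            raise InvalidParameterError(
                f"q_Q + q_q = {self.q_Q + self.q_q} exceeds 1"
            )


@dataclass(frozen=True)
class HaplotypeFreqs:
    """The six marker-QTL haplotype frequencies (must sum to one)."""

    f_MQ: float
    f_Mq: float
    f_Mqp: float
    f_mQ: float
    f_mq: float
    f_mqp: float

    def __post_init__(self):
        for name, v in zip(HAPLOTYPES, self.as_array()):
            if not 0.0 <= v <= 1.0:
                raise InvalidDisequilibriumError(
                    f"haplotype {name} frequency {v} outside [0, 1]"
                )
        s = float(self.as_array().sum())
        if abs(s - 1.0) > 1e-9:
            raise InvalidParameterError(f"haplotype frequencies sum to {s}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_MQ, self.f_Mq, self.f_Mqp, self.f_mQ, self.f_mq, self.f_mqp]
        )

    @classmethod
    def from_array(cls, f) -> "HaplotypeFreqs":
        return cls(*(float(x) for x in f))


@dataclass(frozen=True)
class PhaseWeights:
    """Probabilities of the cis phase for the three double-heterozygote
    classes Mm/Qq (theta1), Mm/Qq+ (theta2) and Mm/qq+ (theta3)."""

    theta1: float
    theta2: float
    theta3: float


def haplotype_frequencies(gp: GeneticParams) -> HaplotypeFreqs:
    """Haplotype frequencies from allele frequencies and disequilibria.

    ``P_MQ = p_M q_Q + D1``, ``P_Mq = p_M q_q + D2`` and so on; any
    frequency falling outside [0, 1] raises
    :class:`~hetmap.errors.InvalidDisequilibriumError` naming the offending
    haplotype (invalid combinations are never silently projected back into
    the simplex).
    """
    p, qQ, qq, d1, d2 = gp.p_M, gp.q_Q, gp.q_q, gp.d1, gp.d2
    qp = 1.0 - qQ - qq
    pm = 1.0 - p
    return HaplotypeFreqs(
        f_MQ=p * qQ + d1,
        f_Mq=p * qq + d2,
        f_Mqp=p * qp - d1 - d2,
        f_mQ=pm * qQ - d1,
        f_mq=pm * qq - d2,
        f_mqp=pm * qp + d1 + d2,
    )


def genetic_params_from_haplotypes(hf: HaplotypeFreqs) -> GeneticParams:
    """Back-solve (p_M, q_Q, q_q, D1, D2) from haplotype frequencies."""
    p = hf.f_MQ + hf.f_Mq + hf.f_Mqp
    qQ = hf.f_MQ + hf.f_mQ
    qq = hf.f_Mq + hf.f_mq
    return GeneticParams(
        p_M=p, q_Q=qQ, q_q=qq, d1=hf.f_MQ - p * qQ, d2=hf.f_Mq - p * qq
    )


def joint_genotype_table(hf: HaplotypeFreqs) -> np.ndarray:
    """3x6 table of joint (marker, QTL) genotype population frequencies.

    Entry ``[m, j]`` is the probability of marker genotype m together with
    QTL genotype j under random union of haplotypes: squared frequencies
    for homozygous diplotypes, twice the product for heterozygous ones, and
    both phase configurations summed in the Mm double-heterozygote cells
    (e.g. Mm/Qq = 2 P_MQ P_mq + 2 P_Mq P_mQ).  The grand sum is one.
    """
    f0, f1, f2, f3, f4, f5 = hf.as_array()  # MQ, Mq, Mq+, mQ, mq, mq+
    table = np.zeros((3, 6))
    # MM row (m=2): both haplotypes carry M.
    table[2, 5] = f0 * f0
    table[2, 4] = 2 * f0 * f1
    table[2, 3] = 2 * f0 * f2
    table[2, 2] = f1 * f1
    table[2, 1] = 2 * f1 * f2
    table[2, 0] = f2 * f2
    # Mm row (m=1): one M- and one m-haplotype; double heterozygotes sum
    # both phases.
    table[1, 5] = 2 * f0 * f3
    table[1, 4] = 2 * f0 * f4 + 2 * f1 * f3
    table[1, 3] = 2 * f0 * f5 + 2 * f2 * f3
    table[1, 2] = 2 * f1 * f4
    table[1, 1] = 2 * f1 * f5 + 2 * f2 * f4
    table[1, 0] = 2 * f2 * f5
    # mm row (m=0): both haplotypes carry m.
    table[0, 5] = f3 * f3
    table[0, 4] = 2 * f3 * f4
    table[0, 3] = 2 * f3 * f5
    table[0, 2] = f4 * f4
    table[0, 1] = 2 * f4 * f5
    table[0, 0] = f5 * f5
    return table


def conditional_qtl_probabilities(hf: HaplotypeFreqs) -> np.ndarray:
    """3x6 table of QTL genotype probabilities conditional on the marker.

    Each row of :func:`joint_genotype_table` divided by its row sum (the
    Hardy-Weinberg marker genotype frequency); rows sum to one.
    """
    joint = joint_genotype_table(hf)
    marg = joint.sum(axis=1)
    if np.any(marg <= 0.0):
        m = int(np.argmin(marg))
        raise DegenerateMarkerError(
            f"marker genotype {MARKER_GENOTYPES[m]} has zero frequency"
        )
    return joint / marg[:, None]


def phase_weights(hf: HaplotypeFreqs) -> PhaseWeights:
    """Cis-phase probabilities for the three double-heterozygote classes.

    theta1 = P_MQ P_mq / (P_MQ P_mq + P_Mq P_mQ), and analogously for the
    Qq+ (theta2) and qq+ (theta3) classes.
    """

    def _theta(cis: float, trans: float, label: str) -> float:
        denom = cis + trans
        if denom <= 0.0:
            raise UndefinedPhaseError(
                f"phase weight {label} is 0/0 (both phase products vanish)"
            )
        return cis / denom

    t1 = _theta(hf.f_MQ * hf.f_mq, hf.f_Mq * hf.f_mQ, "theta1")
    t2 = _theta(hf.f_MQ * hf.f_mqp, hf.f_Mqp * hf.f_mQ, "theta2")
    t3 = _theta(hf.f_Mq * hf.f_mqp, hf.f_Mqp * hf.f_mq, "theta3")
    return PhaseWeights(theta1=t1, theta2=t2, theta3=t3)


# Per-haplotype decomposition: (marker allele index, QTL allele index),
# marker 0=M, 1=m; QTL 0=Q, 1=q, 2=q+.
_HAP_ALLELES = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]


def sample_population(
    gp: GeneticParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n individuals as random unions of two haplotypes.

    Returns an integer array of shape (n, 2): column 0 the marker genotype
    code m and column 1 the QTL genotype code j.  Deterministic given the
    seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    hf = haplotype_frequencies(gp)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    haps = rng.choice(6, size=(n, 2), p=hf.as_array())
    out = np.empty((n, 2), dtype=np.int64)
    alle = np.array(_HAP_ALLELES)
    m_count = (alle[haps][:, :, 0] == 0).sum(axis=1)  # number of M alleles
    out[:, 0] = m_count
    qtl_pairs = alle[haps][:, :, 1]
    a = qtl_pairs.min(axis=1)
    b = qtl_pairs.max(axis=1)
    jmap = np.full((3, 3), -1, dtype=np.int64)
    for (x, y), j in ((((0, 0)), 5), ((0, 1), 4), ((0, 2), 3),
                      ((1, 1), 2), ((1, 2), 1), ((2, 2), 0)):
        jmap[x, y] = j
    out[:, 1] = jmap[a, b]
    return out
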