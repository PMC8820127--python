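"""The codon substitution process.

Muse-Gaudry/Goldman-Yang style 61-state Markov model: a substitution
between sense codons i and j has rate 0 if they differ at more than one
nucleotide position, and otherwise rate proportional to the target codon's
equilibrium frequency pi_j, multiplied by kappa when the single nucleotide
change is a transition (A<->G, C<->T) and by omega = dN/dS when the change
is nonsynonymous. The chain is time-reversible; transition probabilities
are computed through the pi-symmetrized eigendecomposition.

All matrices are ordered by the genetic code's lexicographic sense-codon
list, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .genetic_code import NUCLEOTIDES, STANDARD_CODE, GeneticCode
from .io_formats import CodonAlignment

_FREQ_FLOOR = 1e-6  # floor applied to empirical codon frequencies


@dataclass(frozen=True)
class CodonSubstitutionModel:
    """Parameter bundle (kappa, omega, pi) for a single-class codon model."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if self.omega < 0:
            raise ValidationError("omega must be >= 0")
        pi = np.asarray(self.pi, dtype=float)
        if pi.min() < 0 or abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationError("pi must be nonnegative and sum to 1 within 1e-12")
        object.__setattr__(self, "pi", pi)


class CodonModelStructure:
    """Cached structural arrays for a genetic code.

    ``exch[i, j]`` holds the kappa/omega-free part of the exchangeability:
    0 for multi-nucleotide changes, and flags for transition and
    nonsynonymous status otherwise.
    """

    def __init__(self, code: GeneticCode = STANDARD_CODE):
        self.code = code
        n = code.n_states
        codons = code.sense_codons
        single = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        nonsyn = np.zeros((n, n), dtype=bool)
        ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                diffs = [
                    (codons[i][k], codons[j][k])
                    for k in range(3)
                    if codons[i][k] != codons[j][k]
                ]
                if len(diffs) != 1:
                    continue
                single[i, j] = True
                transition[i, j] = diffs[0] in ts_pairs
                nonsyn[i, j] = code.translate(codons[i]) != code.translate(codons[j])
        self.single = single
        self.transition = transition
        self.nonsyn = nonsyn

    def unscaled_rates(self, kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
        """Off-diagonal rate factors q_ij = pi_j * kappa^ts * omega^ns."""
        q = np.where(self.single, pi[None, :], 0.0)
        q = np.where(self.transition, q * kappa, q)
        q = np.where(self.nonsyn, q * omega, q)
        return q


_STRUCTURES: dict[int, CodonModelStructure] = {}


def get_structure(code: GeneticCode = STANDARD_CODE) -> CodonModelStructure:
    key = id(code)
    if key not in _STRUCTURES:
        _STRUCTURES[key] = CodonModelStructure(code)
    return _STRUCTURES[key]


# ---------------------------------------------------------------------------
# Equilibrium frequencies

FREQUENCY_SCHEMES = ("equal", "F1x4", "F3x4", "F61")


def estimate_codon_frequencies(
    aln: CodonAlignment, scheme: str = "F3x4", code: GeneticCode | None = None
) -> np.ndarray:
    """Equilibrium sense-codon frequencies from an alignment.

    ``equal``: 1/61 each. ``F1x4``: product of overall nucleotide
    frequencies. ``F3x4``: product of position-specific nucleotide
    frequencies (the codeml default). ``F61``: empirical codon counts with
    a 1e-6 floor. Stop-codon mass is redistributed by renormalizing over
    sense codons. Ambiguous codons are excluded from all counts.
    """
    code = code or aln.code
    n = code.n_states
    if scheme not in FREQUENCY_SCHEMES:
        raise ValidationError(f"unknown frequency scheme {scheme!r}")
    if scheme == "equal":
        return np.full(n, 1.0 / n)

    plain = set("ACGT")
    codons = []
    for seq in aln.sequences:
        for s in range(len(seq) // 3):
            codon = seq[3 * s : 3 * s + 3]
            if set(codon) <= plain and codon not in code.stop_codons:
                codons.append(codon)
    if not codons:
        raise EstimationError("no unambiguous codons available for frequency estimation")

    if scheme == "F61":
        counts = np.full(n, 0.0)
        index = {c: i for i, c in enumerate(code.sense_codons)}
        for codon in codons:
            counts[index[codon]] += 1
        freqs = counts / counts.sum()
        freqs = np.maximum(freqs, _FREQ_FLOOR)
        return freqs / freqs.sum()

    if scheme == "F1x4":
        nt = np.zeros(4)
        for codon in codons:
            for b in codon:
                nt[NUCLEOTIDES.index(b)] += 1
        nt /= nt.sum()
        pos = np.tile(nt, (3, 1))
    else:  # F3x4
        pos = np.zeros((3, 4))
        for codon in codons:
            for k, b in enumerate(codon):
                pos[k, NUCLEOTIDES.index(b)] += 1
        pos /= pos.sum(axis=1, keepdims=True)

    freqs = np.array(
        [
            pos[0, NUCLEOTIDES.index(c[0])]
            * pos[1, NUCLEOTIDES.index(c[1])]
            * pos[2, NUCLEOTIDES.index(c[2])]
            for c in code.sense_codons
        ]
    )
    if freqs.sum() <= 0:
        raise EstimationError("degenerate nucleotide composition")
    freqs = np.maximum(freqs / freqs.sum(), _FREQ_FLOOR)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities


def build_codon_rate_matrix(
    model: CodonSubstitutionModel, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Scaled rate matrix Q with stationary mean rate 1.

    Rows sum to zero; the scaling makes branch lengths read as expected
    substitutions per codon site at stationarity.
    """
    struct = get_structure(code)
    q = struct.unscaled_rates(model.kappa, model.omega, model.pi)
    np.fill_diagonal(q, 0.0)
    diag = q.sum(axis=1)
    rate = float(model.pi @ diag)
    if rate <= 0:
        raise ValidationError("rate matrix has zero mean rate")
    q = q / rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition of a reversible Q for fast P(t) = A e^{Lt} B."""

    eigenvalues: np.ndarray  # (n,)
    left: np.ndarray  # A = D^{-1/2} U, shape (n, n)
    right: np.ndarray  # B = U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValidationError("branch length must be >= 0")
        e = np.exp(self.eigenvalues * t)
        p = (self.left * e[None, :]) @ self.right
        return np.clip(p, 0.0, None)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for a vector of branch lengths, shape (m, n, n)."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValidationError("branch lengths must be >= 0")
        e = np.exp(np.multiply.outer(ts, self.eigenvalues))  # (m, n)
        p = np.matmul(self.left[None, :, :] * e[:, None, :], self.right[None, :, :])
        return np.clip(p, 0.0, None)


def decompose_rate_matrix(q: np.ndarray, pi: np.ndarray) -> SpectralDecomposition:
    """Symmetrize with diag(pi)^{1/2}, eigendecompose, clip eigenvalues <= 0.

    Frequencies are floored at a tiny value for the similarity transform
    only, so sparse F3x4/F61 vectors cannot divide by zero.
    """
    d = np.sqrt(np.maximum(pi, 1e-300))
    s = q * d[:, None] / d[None, :]
    s = (s + s.T) / 2.0
    lam, u = np.linalg.eigh(s)
    lam = np.minimum(lam, 0.0)
    return SpectralDecomposition(
        eigenvalues=lam, left=u / d[:, None], right=(u * d[:, None]).T
    )


def transition_probability_matrix(
    q: np.ndarray, t: float, pi: np.ndarray | None = None
) -> np.ndarray:
    """P(t) = exp(Qt), rows summing to 1 within 1e-10, entries clipped at 0.

    Uses the reversible eigendecomposition when ``pi`` is given, otherwise
    a generic scaling-and-squaring matrix exponential.
    """
    if t < 0:
        raise ValidationError("branch length must be >= 0")
    if pi is not None:
        return decompose_rate_matrix(q, pi).transition_matrix(t)
    from scipy.linalg import expm

    return np.clip(expm(q * t), 0.0, None)
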