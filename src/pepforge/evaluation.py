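"""Ensemble scoring against a reference structure.

Ensemble accuracy is the RMSD of the best-fit conformer among the first
``size`` members of the ensemble, so accuracy-versus-size curves can be read
off one generated ensemble.  A prediction counts as a success when that
best-fit RMSD beats a size-dependent cutoff

    rmsd_C(n) = prefactor · [1 + ln(n / n0)]        (n0 = 3, prefactor 1.0 Å)

which grows logarithmically with peptide length n: 1.0 Å at 3 residues,
3.3 Å at 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EvaluationError
from .geometry import ensemble_rmsd
from .structure_io import PeptideChain


@dataclass(frozen=True)
class SuccessCriterion:
    """Size-dependent RMSD success cutoff."""

    n0: int = 3
    prefactor: float = 1.0  # Å

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise EvaluationError("n0 must be >= 1")


def size_dependent_cutoff(n: int, crit: SuccessCriterion = SuccessCriterion()) -> float:
    """Success cutoff in Å for a peptide of ``n`` residues."""
    if n < 1:
        raise EvaluationError(f"peptide length must be >= 1, got {n}")
    return crit.prefactor * (1.0 + math.log(n / crit.n0))


@dataclass
class EnsembleAccuracy:
    """Best-fit RMSD and success flag per ensemble-size prefix."""

    peptide_length: int
    mode: str
    cutoff: float
    best_rmsd_by_size: dict[int, float] = field(default_factory=dict)
    success_by_size: dict[int, bool] = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.best_rmsd_by_size)


def _conformers(ensemble) -> list[PeptideChain]:
    return ensemble.conformers if hasattr(ensemble, "conformers") else list(ensemble)


def best_fit_rmsd(ensemble, reference: PeptideChain, mode: str = "ca",
                  size: int | None = None) -> float:
    """Minimum RMSD between the reference and the first ``size`` conformers."""
    conformers = _conformers(ensemble)
    size = len(conformers) if size is None else size
    if not 1 <= size <= len(conformers):
        raise EvaluationError(f"size must be in [1, {len(conformers)}], got {size}")
    return min(ensemble_rmsd(c, reference, mode) for c in conformers[:size])


def evaluate_peptide(ensemble, reference: PeptideChain, sizes,
                     mode: str = "ca",
                     crit: SuccessCriterion = SuccessCriterion()) -> EnsembleAccuracy:
    """Accuracy/success per ensemble-size prefix (single pass over conformers)."""
    conformers = _conformers(ensemble)
    sizes = sorted(sizes)
    if not sizes or sizes[0] < 1 or sizes[-1] > len(conformers):
        raise EvaluationError(f"sizes must lie in [1, {len(conformers)}]")
    n = len(reference)
    cutoff = size_dependent_cutoff(n, crit)
    result = EnsembleAccuracy(n, mode, cutoff)
    best = math.inf
    targets = set(sizes)
    for k, conf in enumerate(conformers[:sizes[-1]], start=1):
        best = min(best, ensemble_rmsd(conf, reference, mode))
        if k in targets:
            result.best_rmsd_by_size[k] = best
            result.success_by_size[k] = best < cutoff
    return result


def success_rate(results: list[EnsembleAccuracy], size: int) -> float:
    """Fraction of peptides whose ensemble succeeds at the given size."""
    if not results:
        raise EvaluationError("success_rate needs at least one evaluated peptide")
    flags = []
    for r in results:
        if size not in r.success_by_size:
            raise EvaluationError(f"size {size} was not evaluated for a peptide")
        flags.append(r.success_by_size[size])
    return sum(flags) / len(flags)
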