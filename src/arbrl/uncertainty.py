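"""Per-trial uncertainty of each control strategy.

Model-based uncertainty chi_MB tracks the history of state-prediction errors
with a decayed-count Dirichlet posterior over discretized SPE magnitudes:
reliability is the posterior mean probability of the lowest-SPE category and
chi_MB = 1 - reliability. Model-free uncertainty chi_MF is Pearce-Hall
associability: a running average of normalized |RPE| (surprise), bounded in
[0, 1] by dividing through the maximum coin value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default SPE category edges: low [0, 0.45), medium [0.45, 0.7), high [0.7, 1].
#: The low/medium boundary sits below the chance-level SPE of 0.5 so that
#: transitions predicted better than chance count as reliable evidence.
DEFAULT_SPE_EDGES = (0.45, 0.7)
#: default forgetting factor; the effective sample size 1/(1 - lam) spans a
#: few trials so the reliability estimate can track the task's short blocks.
DEFAULT_FORGETTING = 0.7
R_MAX = 40.0


@dataclass
class SpePosterior:
    """Decayed pseudo-counts over K discretized SPE categories.

    Every update multiplies all counts by the forgetting factor ``lam`` and
    adds 1 to the observed category, so the effective sample size converges to
    1 / (1 - lam) for lam < 1.
    """

    lam: float = DEFAULT_FORGETTING
    edges: tuple[float, ...] = DEFAULT_SPE_EDGES
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("forgetting factor must lie in (0, 1]")
        if self.counts is None:
            self.counts = np.ones(len(self.edges) + 1)
        if np.any(self.counts <= 0):
            raise ValueError("pseudo-counts must be positive")

    @property
    def category_means(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def chi_mb(self) -> float:
        return 1.0 - float(self.counts[0] / self.counts.sum())

    def bin_of(self, spe: float) -> int:
        if not 0.0 <= spe <= 1.0:
            raise ValueError(f"SPE must lie in [0, 1], got {spe}")
        return int(np.searchsorted(np.asarray(self.edges), spe, side="right"))

    def copy(self) -> "SpePosterior":
        return SpePosterior(lam=self.lam, edges=self.edges, counts=self.counts.copy())


def update_mb_uncertainty(post: SpePosterior, spe: float) -> float:
    """Assimilate one SPE and return the updated chi_MB.

    Counts decay by ``lam``, the observed SPE category gains one count, and
    chi_MB = 1 - posterior mean of the lowest-SPE category. Updates in place.
    """
    k = post.bin_of(spe)
    post.counts *= post.lam
    post.counts[k] += 1.0
    return post.chi_mb


@dataclass
class Associability:
    """Pearce-Hall associability: running mean of normalized surprise."""

    a: float = 0.5
    eta_ph: float = 0.2
    r_max: float = R_MAX

    def __post_init__(self) -> None:
        if not 0.0 < self.eta_ph <= 1.0:
            raise ValueError("Pearce-Hall rate must lie in (0, 1]")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("associability must start in [0, 1]")


def update_mf_uncertainty(assoc: Associability, rpe: float) -> float:
    """Assimilate one RPE and return the updated chi_MF.

    Surprise u = min(|RPE| / r_max, 1); associability moves toward u at the
    Pearce-Hall rate. Updates in place.
    """
    u = min(abs(rpe) / assoc.r_max, 1.0)
    assoc.a += assoc.eta_ph * (u - assoc.a)
    return assoc.a


def max_uncertainty(chi_mb: float, chi_mf: float) -> float:
    """Uncertainty of whichever strategy is currently the most uncertain."""
    if not (0.0 <= chi_mb <= 1.0 and 0.0 <= chi_mf <= 1.0):
        raise ValueError("uncertainties must lie in [0, 1]")
    return max(chi_mb, chi_mf)
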