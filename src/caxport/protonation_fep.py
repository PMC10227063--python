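"""Free-energy bookkeeping for side-chain protonation analyses.

A dual-topology alchemical transformation between protonated and
deprotonated states is discretized into lambda windows; in each window the
potential-energy difference to the next state, dU (in kT), is sampled along
a trajectory.  Exponential averaging (the free-energy perturbation
estimator) gives the per-window free energy

    dG_w = -ln < exp(-dU) >            (kT units)

and the path total is the sum over windows.  The transformation is run in
both directions; the reported value is the mean of the two direction
estimates and the half-difference is the quoted error.  Because each
transformation simultaneously protonates the protein side chain and
deprotonates a reference amino acid free in solution (or is directly
differenced against a solution-side calculation), the resulting ddG measures
the protonation propensity of the protein site relative to the same side
chain in solution.  Negative ddG means protonation is favoured in the
protein, i.e. an upward shift of the apparent pKa:

    pKa shift = -ddG / (RT ln 10)      (+1 pH unit per -1.364 kcal/mol at 298 K)

Energies are handled in kT internally; conversion to kcal/mol happens only
at reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FepWindow",
    "FepDataset",
    "FreeEnergyResult",
    "ProtonationContext",
    "discard_equilibration",
    "exp_free_energy",
    "bar_free_energy",
    "total_free_energy",
    "combine_bidirectional",
    "protonation_ddg",
    "ddg_to_pka_shift",
    "pka_shift_to_ddg",
    "PROTONATION_REFERENCE",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720e-3


@dataclass
class FepWindow:
    """Per-window energy-difference samples (kT) with an equilibration mask."""

    lambda_index: int
    direction: str  # "forward" or "reverse"
    samples: np.ndarray
    equil_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.equil_mask is None:
            self.equil_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.equil_mask = np.asarray(self.equil_mask, dtype=bool).ravel()
            if self.equil_mask.size != self.samples.size:
                raise ValueError("equilibration mask length mismatch")

    @property
    def production(self) -> np.ndarray:
        """Samples that survive the equilibration discard."""
        return self.samples[~self.equil_mask]


@dataclass
class FepDataset:
    """Ordered lambda windows for one site, possibly in both directions."""

    windows: list[FepWindow]
    temperature: float = 298.0
    site_label: str = ""

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset needs at least one window")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for w in self.windows:
            if w.production.size < 2:
                raise ValueError(
                    f"window {w.lambda_index} ({w.direction}) has <2 production samples"
                )

    def direction(self, direction: str) -> list[FepWindow]:
        ws = [w for w in self.windows if w.direction == direction]
        return sorted(ws, key=lambda w: w.lambda_index)


@dataclass
class FreeEnergyResult:
    """A free-energy estimate in kcal/mol with a bidirectional error bar."""

    dg: float
    error: float
    direction_values: dict[str, float] = field(default_factory=dict)
    estimator: str = "exp"
    site_label: str = ""
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg):
            raise ValueError("free energy must be finite")
        if self.error < 0:
            raise ValueError("error must be non-negative")


@dataclass
class ProtonationContext:
    """Which other titratable sites are held fixed, and in which state."""

    fixed_states: dict[str, str] = field(default_factory=dict)

    _SITES = frozenset({"E72", "E255", "H256", "E233", "H226"})

    def __post_init__(self) -> None:
        for site, state in self.fixed_states.items():
            if site not in self._SITES:
                raise ValueError(f"unknown site label {site!r}")
            if state not in ("protonated", "deprotonated"):
                raise ValueError(f"invalid state {state!r} for {site}")


# -- estimators ------------------------------------------------------------


def discard_equilibration(ds: FepDataset, fraction: float) -> FepDataset:
    """Mark the first ceil(fraction * n) samples of each window as equilibration."""
    if not 0.0 <= fraction < 0.9:
        raise ValueError("equilibration fraction must be in [0, 0.9)")
    windows = []
    for w in ds.windows:
        n_eq = math.ceil(fraction * w.samples.size)
        mask = np.zeros(w.samples.size, dtype=bool)
        mask[:n_eq] = True
        if (~mask).sum() < 2:
            raise ValueError(
                f"window {w.lambda_index} left with <2 samples after discard"
            )
        windows.append(replace(w, samples=w.samples.copy(), equil_mask=mask))
    return FepDataset(windows, ds.temperature, ds.site_label)


def exp_free_energy(samples: np.ndarray, temperature: float = 298.0) -> float:
    """Exponential-averaging estimate -ln<exp(-dU)> in kT.

    Uses log-sum-exp, so it is stable for |dU| up to at least 700 kT.
    ``temperature`` is accepted for interface symmetry; samples are already
    in kT so it does not enter the estimate.
    """
    du = np.asarray(samples, dtype=float).ravel()
    if du.size == 0:
        raise ValueError("empty sample array")
    return float(-(logsumexp(-du) - math.log(du.size)))


def bar_free_energy(forward_work: np.ndarray, reverse_work: np.ndarray) -> float:
    """Bennett acceptance ratio estimate (kT) for one window pair.

    ``forward_work`` are dU samples for the A->B perturbation collected in
    state A; ``reverse_work`` are dU samples for B->A collected in state B.
    Solves the self-consistent BAR equation by bracketing in dG.
    """
    wf = np.asarray(forward_work, dtype=float).ravel()
    wr = np.asarray(reverse_work, dtype=float).ravel()
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both directions need samples")
    m = math.log(wf.size / wr.size)

    def implicit(dg: float) -> float:
        lf = logsumexp(-np.logaddexp(0.0, m + wf - dg))
        lr = logsumexp(-np.logaddexp(0.0, -m + wr + dg))
        return lf - lr

    lo = min(exp_free_energy(wf), -exp_free_energy(wr)) - 50.0
    hi = max(exp_free_energy(wf), -exp_free_energy(wr)) + 50.0
    return float(brentq(implicit, lo, hi, xtol=1e-10))


def total_free_energy(ds: FepDataset, estimator: str = "exp") -> dict[str, float]:
    """Per-direction path totals in kcal/mol.

    Both entries estimate the same physical forward free energy: the
    reverse-path sum is negated so that, for noiseless data, forward and
    reverse agree.  With ``estimator="bar"`` each window pair combines the
    forward samples with the matching reverse-window samples.
    """
    if estimator not in ("exp", "bar"):
        raise ValueError(f"unknown estimator {estimator!r}")
    kt_to_kcal = GAS_CONSTANT_KCAL * ds.temperature
    fwd = ds.direction("forward")
    rev = ds.direction("reverse")
    out: dict[str, float] = {}
    if estimator == "exp":
        if fwd:
            out["forward"] = kt_to_kcal * sum(exp_free_energy(w.production) for w in fwd)
        if rev:
            out["reverse"] = -kt_to_kcal * sum(exp_free_energy(w.production) for w in rev)
        if not out:
            raise ValueError("dataset has no windows in either direction")
        return out
    # BAR needs both directions, matched window for window along the path.
    if not fwd or not rev:
        raise ValueError("BAR requires both forward and reverse windows")
    if len(fwd) != len(rev):
        raise ValueError("inconsistent window count between directions")
    n = len(fwd)
    total_kt = 0.0
    for i, wf in enumerate(fwd):
        # reverse window n-1-i covers the same adjacent-state pair.
        wr = rev[n - 1 - i]
        total_kt += bar_free_energy(wf.production, wr.production)
    out["forward"] = out["reverse"] = kt_to_kcal * total_kt
    return out


def combine_bidirectional(forward: float, reverse: float) -> FreeEnergyResult:
    """Mean of the two direction estimates; half-difference as the error bar."""
    if not (math.isfinite(forward) and math.isfinite(reverse)):
        raise ValueError("direction estimates must be finite")
    return FreeEnergyResult(
        dg=0.5 * (forward + reverse),
        error=0.5 * abs(forward - reverse),
        direction_values={"forward": forward, "reverse": reverse},
    )


def estimate(ds: FepDataset, estimator: str = "exp") -> FreeEnergyResult:
    """Convenience: per-direction totals combined into one result."""
    totals = total_free_energy(ds, estimator=estimator)
    if len(totals) == 2:
        res = combine_bidirectional(totals["forward"], totals["reverse"])
    else:
        (value,) = totals.values()
        res = FreeEnergyResult(dg=value, error=0.0, direction_values=dict(totals))
    res.estimator = estimator
    res.site_label = ds.site_label
    res.temperature = ds.temperature
    return res


# -- thermodynamic cycle ---------------------------------------------------


def _residue_type(label: str) -> str:
    head = "".join(ch for ch in label if ch.isalpha())
    return head[:1].upper()


def protonation_ddg(
    protein: FreeEnergyResult, solution_reference: FreeEnergyResult
) -> FreeEnergyResult:
    """ddG = dG(protein site) - dG(solution side chain), errors in quadrature.

    Negative ddG means protonation is favoured in the protein relative to
    solution (upshifted apparent pKa).
    """
    if protein.site_label and solution_reference.site_label:
        if _residue_type(protein.site_label) != _residue_type(solution_reference.site_label):
            raise ValueError(
                "protein site and solution reference are different side-chain types: "
                f"{protein.site_label!r} vs {solution_reference.site_label!r}"
            )
    if protein.temperature != solution_reference.temperature:
        raise ValueError("temperature mismatch between cycle legs")
    return FreeEnergyResult(
        dg=protein.dg - solution_reference.dg,
        error=math.hypot(protein.error, solution_reference.error),
        direction_values={},
        estimator=protein.estimator,
        site_label=protein.site_label,
        temperature=protein.temperature,
    )


def ddg_to_pka_shift(ddg: float, temperature: float = 298.0) -> float:
    """Apparent-pKa shift (pH units) for a protonation ddG in kcal/mol.

    shift = -ddG / (RT ln 10); at 298 K one pH unit corresponds to
    -1.364 kcal/mol (-1.4 to two significant figures).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -ddg / (GAS_CONSTANT_KCAL * temperature * math.log(10.0))


def pka_shift_to_ddg(shift: float, temperature: float = 298.0) -> float:
    """Inverse of :func:`ddg_to_pka_shift`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -shift * GAS_CONSTANT_KCAL * temperature * math.log(10.0)


#: Reference protonation ddG values (kcal/mol) for the inward-facing YfkE
#: crystal structure, from membrane-protein MD with 40-window bidirectional
#: FEP.  Shipped as an annotation the pipeline can render next to its own
#: desk-scale results; these numbers require the full MD setup and are not
#: recomputed here.
PROTONATION_REFERENCE: list[dict[str, object]] = [
    {"site": "E72", "context": "single protonation", "ddg": -11.5, "error": 0.5},
    {"site": "E255", "context": "single protonation", "ddg": -7.1, "error": 0.4},
    {"site": "H256", "context": "single protonation", "ddg": 0.3, "error": 0.1},
    {"site": "E233", "context": "single protonation", "ddg": -0.5, "error": 0.1},
    {"site": "H226", "context": "single protonation", "ddg": 0.9, "error": 0.1},
    {"site": "E255", "context": "with E72 protonated", "ddg": -5.1, "error": 0.6},
    {"site": "H256", "context": "with E72 protonated", "ddg": 1.8, "error": 0.7},
    {"site": "H256", "context": "with E72, E255 protonated", "ddg": 3.3, "error": 1.2},
    {"site": "E233", "context": "with E72, E255 protonated", "ddg": -0.2, "error": 0.1},
    {"site": "H226", "context": "with E72, E255 protonated", "ddg": 0.3, "error": 0.3},
]
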