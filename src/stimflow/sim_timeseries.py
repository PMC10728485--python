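"""Sigmoid-dynamics time-series simulator with ground-truth cell times.

Each simulated cell has a hidden continuous time t: in discrete mode,
its capture timepoint plus Gaussian asynchrony noise; in continuous
mode, a uniform draw over a time range.  Each gene follows a sigmoid
trajectory S(t | alpha, beta) = 1 / (1 + exp(-(t - alpha) / beta)) —
either monotonic, or "complex" (activation followed by deactivation,
S(t) - S(t - t_switch)).  Trajectories are min-max normalized per gene
over the sampled cells before Gaussian expression noise is added.

Recovery of cell ordering by a pseudotime method is evaluated against
the hidden true time with Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats


class InvalidParameterError(ValueError):
    """Raised for dynamics parameters outside their valid domain."""


@dataclass(frozen=True)
class GeneDynamicsSpec:
    """Parameters of one gene's sigmoid trajectory.

    ``alpha`` is the activation midpoint, ``beta`` the width;
    ``t_switch`` (complex genes only) shifts a second, subtracted
    sigmoid that deactivates the gene.  ``direction`` mirrors the
    trajectory for down-regulated genes (1 - value).
    """

    kind: str  # "monotonic" | "complex"
    alpha: float
    beta: float
    t_switch: float | None = None
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.kind not in ("monotonic", "complex"):
            raise InvalidParameterError(f"unknown kind {self.kind!r}")
        if self.direction not in ("up", "down"):
            raise InvalidParameterError(f"unknown direction {self.direction!r}")
        if self.beta <= 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if self.kind == "complex" and self.t_switch is None:
            raise InvalidParameterError("complex genes require t_switch")
        if self.kind == "monotonic" and self.t_switch is not None:
            raise InvalidParameterError("t_switch only valid for complex genes")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a simulated capture experiment."""

    gene_specs: tuple[GeneDynamicsSpec, ...]
    sampling: str = "discrete"  # "discrete" | "continuous"
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    cells_per_timepoint: int = 250
    asynchrony_sd: float = 1.5
    expression_noise_sd: float = 0.05
    t_range: tuple[float, float] = (0.0, 20.0)
    n_cells_continuous: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_specs) == 0:
            raise ValueError("gene_specs must be non-empty")
        if self.sampling not in ("discrete", "continuous"):
            raise ValueError(f"unknown sampling {self.sampling!r}")
        if self.cells_per_timepoint <= 0:
            raise ValueError("cells_per_timepoint must be > 0")
        if self.asynchrony_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        tp = np.asarray(self.timepoints)
        if len(tp) and not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_specs)


@dataclass
class SimulatedDataset:
    """Simulated expression plus the hidden per-cell true time."""

    expression: np.ndarray  # cells x genes
    true_time: np.ndarray  # hidden continuous t per cell
    capture_label: np.ndarray  # discrete timepoint index per cell
    spec: SimulationSpec

    def __post_init__(self) -> None:
        if not np.isfinite(self.true_time).all():
            raise ValueError("true_time must be finite")
        if self.expression.shape[0] != self.true_time.shape[0]:
            raise ValueError("expression and true_time disagree on cell count")


def sigmoid_value(t, spec: GeneDynamicsSpec) -> np.ndarray:
    """Noise-free trajectory value(s) in [0, 1] at time(s) ``t``.

    Monotonic: S(t | alpha, beta); complex: S(t) - S(t - t_switch);
    direction ``down`` mirrors either as 1 - value.
    """
    t = np.asarray(t, dtype=float)

    def S(x):
        return 1.0 / (1.0 + np.exp(-(x - spec.alpha) / spec.beta))

    if spec.kind == "monotonic":
        value = S(t)
    else:
        value = S(t) - S(t - spec.t_switch)
    if spec.direction == "down":
        value = 1.0 - value
    return value


def random_gene_specs(
    n_genes: int,
    rng: np.random.Generator,
    frac_complex: float = 0.5,
    frac_down: float = 0.5,
    alpha_range: tuple[float, float] = (0.0, 20.0),
    beta_range: tuple[float, float] = (0.5, 3.0),
    t_switch_range: tuple[float, float] = (5.0, 15.0),
) -> tuple[GeneDynamicsSpec, ...]:
    """Sample gene dynamics with a configurable kind/direction mix.

    Deterministic counts: the first round(frac_complex * n) genes are
    complex, and directions alternate to hit frac_down, so small
    simulations always contain both shapes.
    """
    n_complex = int(round(frac_complex * n_genes))
    n_down = int(round(frac_down * n_genes))
    kinds = ["complex"] * n_complex + ["monotonic"] * (n_genes - n_complex)
    # alternate directions so both kinds receive both directions
    directions = ["up"] * n_genes
    for j, i in enumerate(list(range(0, n_genes, 2)) + list(range(1, n_genes, 2))):
        if j < n_down:
            directions[i] = "down"
    specs = []
    for kind, direction in zip(kinds, directions):
        specs.append(
            GeneDynamicsSpec(
                kind=kind,
                alpha=float(rng.uniform(*alpha_range)),
                beta=float(rng.uniform(*beta_range)),
                t_switch=float(rng.uniform(*t_switch_range)) if kind == "complex" else None,
                direction=direction,
            )
        )
    return tuple(specs)


def default_simulation_spec(
    n_genes: int = 20,
    seed: int = 0,
    sampling: str = "discrete",
    frac_complex: float = 0.5,
    frac_down: float = 0.5,
) -> SimulationSpec:
    """The default 4-timepoint capture: 250 cells each at t = 0, 5, 10, 20,
    asynchrony SD 1.5, expression noise SD 0.05, mixed gene dynamics."""
    rng = np.random.default_rng(seed)
    return SimulationSpec(
        gene_specs=random_gene_specs(
            n_genes, rng, frac_complex=frac_complex, frac_down=frac_down
        ),
        sampling=sampling,
        seed=seed,
    )


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw cells, evaluate gene trajectories at hidden times, add noise.

    Discrete mode: ``cells_per_timepoint`` cells per capture time, each
    with hidden t = capture time + Gaussian(0, asynchrony_sd), not
    clipped.  Continuous mode: t ~ Uniform(t_range) for
    ``n_cells_continuous`` cells; capture labels are assigned by the
    nearest capture timepoint.  Trajectory values are min-max
    normalized per gene over the sampled cells before Gaussian
    expression noise is added.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sampling == "discrete":
        capture = np.repeat(np.arange(len(spec.timepoints)), spec.cells_per_timepoint)
        base_t = np.asarray(spec.timepoints)[capture]
        true_time = base_t + rng.normal(0.0, spec.asynchrony_sd, size=base_t.shape)
    else:
        true_time = rng.uniform(*spec.t_range, size=spec.n_cells_continuous)
        tp = np.asarray(spec.timepoints)
        capture = np.abs(true_time[:, None] - tp[None, :]).argmin(axis=1)

    expr = np.column_stack([sigmoid_value(true_time, g) for g in spec.gene_specs])
    lo = expr.min(axis=0, keepdims=True)
    span = expr.max(axis=0, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        expr = np.where(span > 0, (expr - lo) / np.where(span > 0, span, 1.0), 0.0)
    if spec.expression_noise_sd > 0:
        expr = expr + rng.normal(0.0, spec.expression_noise_sd, size=expr.shape)
    return SimulatedDataset(
        expression=expr,
        true_time=true_time,
        capture_label=capture.astype(int),
        spec=spec,
    )


def evaluate_order_recovery(true_time: np.ndarray, pt: np.ndarray) -> float:
    """Spearman rank correlation between hidden true time and pseudotime."""
    true_time = np.asarray(true_time, dtype=float).ravel()
    pt = np.asarray(pt, dtype=float).ravel()
    if len(true_time) != len(pt):
        raise ValueError("vectors must have equal length")
    if len(true_time) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(true_time) == 0 or np.ptp(pt) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(true_time, pt).statistic
    return float(rho)


def spec_to_dict(spec: SimulationSpec) -> dict:
    """Plain-dict form of a simulation spec (for YAML round trips)."""
    d = asdict(spec)
    d["gene_specs"] = [asdict(g) for g in spec.gene_specs]
    d["timepoints"] = list(spec.timepoints)
    d["t_range"] = list(spec.t_range)
    return d


def spec_from_dict(d: dict) -> SimulationSpec:
    """Inverse of :func:`spec_to_dict`."""
    d = dict(d)
    d["gene_specs"] = tuple(GeneDynamicsSpec(**g) for g in d["gene_specs"])
    d["timepoints"] = tuple(d["timepoints"])
    d["t_range"] = tuple(d["t_range"])
    return SimulationSpec(**d)
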