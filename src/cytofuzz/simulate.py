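"""Synthetic well-plate trajectories and expression matrices.

The generator emulates a 96-well CD4+ T-cell expansion experiment: cells are
seeded on day 0, sit through a 3-day post-thaw lag (media acclimation and
post-activation anergy), then grow exponentially at a condition-specific rate
until a confluence ceiling, after which the culture declines.  Observed
concentrations carry hemocytometer counting noise (Poisson on the counted
cells) and a multiplicative well-to-well lognormal error; each replicate
dataset carries a lognormal batch factor on the growth rate, which is what the
per-dataset rate normalization downstream exists to remove.

The ground-truth dose-response surface combines per-cytokine Hill activation
with an IL-2 x IL-7 synergy that saturates and then over-stimulates (cell-death
pathways dominating at high combined doses), IL-15 benefit that is competed
away by IL-2 (shared receptor chain), and a steep high-IL-15 self-inhibition::

    h_i  = d_i^n / (K_i^n + d_i^n)                     (activation Hill terms)
    g15  = d15^m / (K_inh^m + d15^m)                   (steep inhibition term)
    G(d) = G0 + a2*h2 + a7*h7 + a15*h15*(1 - h2)
              + s27*h2*h7 - o27*(h2*h7)^2 - q*g15      (clipped at 0)

With the default parameters the top true rates belong to conditions
110, 200, 020 and 011, the all-high condition 222 is mediocre, and high IL-15
alone (002) is among the worst — the qualitative structure the downstream
statistics are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import validate_design

COUNT_COLUMNS = ("dataset", "key", "well", "day", "cells_per_ml")


@dataclass
class SimulationConfig:
    """Ground-truth surface parameters and noise model for the generator.

    Rates are hr^-1, doses and Hill constants ng/mL, concentrations cells/mL.
    ``counting_volume_ml=None`` disables the Poisson counting step (an ideal,
    infinite-volume counter).
    """

    # dose-response surface
    g0: float = 0.010          # baseline rate, no cytokines
    a2: float = 0.012          # IL-2 Hill amplitude
    a7: float = 0.012          # IL-7 Hill amplitude
    a15: float = 0.0075        # IL-15 Hill amplitude (scaled by 1 - h2)
    s27: float = 0.008         # IL-2 x IL-7 synergy
    o27: float = 0.035         # IL-2 x IL-7 over-stimulation penalty
    q: float = 0.010           # high-IL-15 inhibition depth
    k2: float = 5.0
    k7: float = 25.0
    k15: float = 30.0
    hill_n: float = 2.0
    k15_inhib: float = 60.0    # half-point of the high-IL-15 inhibition
    m_inhib: float = 4.0       # steepness of the inhibition Hill
    # culture dynamics
    lag_days: int = 3
    seeding_cells_per_ml: float = 166_667.0
    well_volume_ml: float = 0.300
    confluence_ceiling: float = 2.5e6
    decline_per_day: float = 0.20
    n_days: int = 7
    # noise model
    counting_volume_ml: float | None = 4e-4   # 4 hemocytometer squares
    well_cv: float = 0.10
    batch_sd: float = 0.15                    # SD of log batch factor on rate
    # layout
    n_datasets: int = 4
    wells_per_condition: int = 4
    seed: int = 0

    def validate(self) -> None:
        pos = {
            "k2": self.k2, "k7": self.k7, "k15": self.k15,
            "hill_n": self.hill_n, "k15_inhib": self.k15_inhib,
            "m_inhib": self.m_inhib,
            "seeding_cells_per_ml": self.seeding_cells_per_ml,
            "confluence_ceiling": self.confluence_ceiling,
        }
        for name, value in pos.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        nonneg = {
            "g0": self.g0, "a2": self.a2, "a7": self.a7, "a15": self.a15,
            "well_cv": self.well_cv, "batch_sd": self.batch_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.confluence_ceiling <= self.seeding_cells_per_ml:
            raise ValueError("confluence ceiling must exceed seeding concentration")
        if self.counting_volume_ml is not None and self.counting_volume_ml <= 0:
            raise ValueError("counting_volume_ml must be > 0 or None")
        if self.n_datasets < 1 or self.wells_per_condition < 1:
            raise ValueError("need at least one dataset and one well per condition")
        if not 0 <= self.decline_per_day < 1:
            raise ValueError("decline_per_day must lie in [0, 1)")
        if self.lag_days < 0 or self.n_days <= self.lag_days:
            raise ValueError("need 0 <= lag_days < n_days")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def seeded_cells_per_well(config: SimulationConfig | None = None) -> float:
    """Cells plated per well: seeding concentration times plated volume."""
    config = config or SimulationConfig()
    return config.seeding_cells_per_ml * config.well_volume_ml


def true_growth_rate(dose, config: SimulationConfig | None = None):
    """Ground-truth exponential growth rate (hr^-1) at a cytokine dose.

    ``dose`` is an (il2, il7, il15) triple in ng/mL, or an (N, 3) array.
    """
    config = config or SimulationConfig()
    config.validate()
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    d2, d7, d15 = d[..., 0], d[..., 1], d[..., 2]
    n = config.hill_n

    def hill(x, k, exponent):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x > 0, x**exponent / (k**exponent + x**exponent), 0.0)
        return out

    h2 = hill(d2, config.k2, n)
    h7 = hill(d7, config.k7, n)
    h15 = hill(d15, config.k15, n)
    g15 = hill(d15, config.k15_inhib, config.m_inhib)
    rate = (
        config.g0
        + config.a2 * h2
        + config.a7 * h7
        + config.a15 * h15 * (1.0 - h2)
        + config.s27 * h2 * h7
        - config.o27 * (h2 * h7) ** 2
        - config.q * g15
    )
    return np.maximum(rate, 0.0) if rate.ndim else float(max(rate, 0.0))


def _latent_trajectory(rate_per_hr: float, config: SimulationConfig) -> np.ndarray:
    """Noise-free concentration per day 0..n_days for one condition.

    Exponential at ``rate_per_hr`` after the lag, hard-capped at the
    confluence ceiling; once capped, the culture declines by
    ``decline_per_day`` per day.
    """
    days = config.n_days + 1
    c = np.empty(days)
    c[: config.lag_days + 1] = config.seeding_cells_per_ml
    capped = False
    for t in range(config.lag_days, config.n_days):
        if capped:
            c[t + 1] = c[t] * (1.0 - config.decline_per_day)
        else:
            grown = c[t] * np.exp(24.0 * rate_per_hr)
            if grown >= config.confluence_ceiling:
                c[t + 1] = config.confluence_ceiling
                capped = True
            else:
                c[t + 1] = grown
    return c


def simulate_trajectories(
    design: pd.DataFrame, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Simulate a long-format well-count table for every dataset/condition/well.

    Columns: dataset, key, well, day, cells_per_ml.  Reproducible under a
    fixed ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    validate_design(design)
    rng = np.random.default_rng(config.seed)

    doses = design[["il2_ng_ml", "il7_ng_ml", "il15_ng_ml"]].to_numpy(dtype=float)
    base_rates = np.atleast_1d(true_growth_rate(doses, config))
    keys = design["key"].tolist()

    sigma_well = float(np.sqrt(np.log1p(config.well_cv**2)))
    records: list[tuple] = []
    for ds in range(config.n_datasets):
        eps = rng.normal(0.0, config.batch_sd) if config.batch_sd > 0 else 0.0
        batch = float(np.exp(eps))
        for key, rate in zip(keys, base_rates):
            latent = _latent_trajectory(rate * batch, config)
            for well in range(config.wells_per_condition):
                for day, conc in enumerate(latent):
                    obs = conc
                    if config.counting_volume_ml is not None:
                        counted = rng.poisson(conc * config.counting_volume_ml)
                        obs = counted / config.counting_volume_ml
                    if config.well_cv > 0:
                        obs *= np.exp(
                            rng.normal(-0.5 * sigma_well**2, sigma_well)
                        )
                    records.append((ds, key, well, day, obs))
    return pd.DataFrame(records, columns=list(COUNT_COLUMNS))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", dtype={"key": str}, float_precision="round_trip")
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (counts["cells_per_ml"] < 0).any() or not np.isfinite(
        counts["cells_per_ml"]
    ).all():
        raise ValueError("cell concentrations must be finite and >= 0")
    return counts


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionPlan:
    """What `simulate_expression` planted, for downstream test assertions."""

    responders: list[str] = field(default_factory=list)
    outliers: list[str] = field(default_factory=list)
    trackers: dict[str, str] = field(default_factory=dict)  # gene -> condition
    growth_profiles: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_expression(
    design: pd.DataFrame,
    config: SimulationConfig | None = None,
    n_genes: int = 1000,
    seed: int = 0,
    conditions: Sequence[str] = ("000", "200", "020", "002"),
    days: Sequence[int] = (4, 5, 7),
    n_responders: int = 40,
    n_outliers: int = 5,
    n_trackers: int = 6,
    background_sigma: float = 0.15,
    outlier_scale: float = 10.0,
) -> tuple[pd.DataFrame, ExpressionPlan]:
    """Fold-change matrix (genes x condition/day samples) with planted structure.

    Background genes fluctuate around fold change 1 (lognormal, sigma on the
    log scale).  Planted classes:

    * responders — at least +/-50% change (FC >= 1.5 or <= 0.5) in one condition;
    * outliers   — log fold changes at ``outlier_scale`` times the background
      spread in every sample (the PCA screen should flag them);
    * trackers   — day-4/5/7 profile exactly proportional to the condition's
      noise-free growth curve (Pearson r = 1 against the growth profile).

    Returns the matrix (first column ``gene``) and the planting record.
    """
    config = config or SimulationConfig()
    config.validate()
    validate_design(design)
    if n_genes < 20:
        raise ValueError("n_genes must be >= 20")
    n_planted = n_responders + n_outliers + n_trackers
    if n_planted > n_genes // 2:
        raise ValueError(
            f"n_genes={n_genes} too small for {n_planted} planted genes"
        )
    known = set(design["key"])
    bad = [c for c in conditions if c not in known]
    if bad:
        raise ValueError(f"conditions not in design: {bad}")
    if any(d > config.n_days or d <= config.lag_days for d in days):
        raise ValueError("expression days must lie in the growth phase")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"{key}_d{day}" for key in conditions for day in days]
    log_fc = rng.normal(0.0, background_sigma, size=(n_genes, len(samples)))

    plan = ExpressionPlan()
    order = rng.permutation(n_genes)
    idx_resp = order[:n_responders]
    idx_out = order[n_responders : n_responders + n_outliers]
    idx_trk = order[n_responders + n_outliers : n_planted]

    # responders: shift every sample of one condition past the +/-50% boundary
    for i in idx_resp:
        cond = conditions[rng.integers(len(conditions))]
        up = rng.random() < 0.5
        mag = (np.log(1.5) if up else np.log(2.0)) + rng.exponential(0.2)
        cols = [j for j, s in enumerate(samples) if s.startswith(f"{cond}_")]
        shift = mag if up else -mag
        log_fc[i, cols] = shift + rng.normal(0.0, 0.05, size=len(cols))
        log_fc[i, cols[0]] = shift  # anchor: the +/-50% change is guaranteed
        plan.responders.append(genes[i])

    # outliers: extreme profiles inside a shared 2-D profile subspace
    # (co-regulated outlier groups; with > 2 independent extreme directions a
    # 2-component projection could not show them all)
    if n_outliers:
        basis = np.linalg.qr(rng.normal(size=(len(samples), 2)))[0]  # (S, 2)
        for i in idx_out:
            theta = rng.uniform(0, 2 * np.pi)
            direction = basis @ np.array([np.cos(theta), np.sin(theta)])
            log_fc[i, :] = (
                outlier_scale * background_sigma * np.sqrt(len(samples)) * direction
                + rng.normal(0.0, 0.2 * background_sigma, size=len(samples))
            )
            plan.outliers.append(genes[i])

    # trackers: exactly proportional to the condition's latent growth curve
    dose_by_key = {
        row["key"]: (row["il2_ng_ml"], row["il7_ng_ml"], row["il15_ng_ml"])
        for _, row in design.iterrows()
    }
    for j, i in enumerate(idx_trk):
        cond = conditions[j % len(conditions)]
        rate = true_growth_rate(dose_by_key[cond], config)
        latent = _latent_trajectory(rate, config)
        profile = latent[list(days)]
        scale = float(rng.uniform(0.5, 2.0)) / profile.max()
        cols = [samples.index(f"{cond}_d{day}") for day in days]
        log_fc[i, cols] = np.log(scale * profile)
        plan.trackers[genes[i]] = cond
        plan.growth_profiles[genes[i]] = profile.copy()

    matrix = pd.DataFrame(np.exp(log_fc), columns=samples)
    matrix.insert(0, "gene", genes)
    return matrix, plan


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if expr.columns[0] != "gene":
        raise ValueError("expression table must have 'gene' as first column")
    values = expr.iloc[:, 1:].to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    return expr
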