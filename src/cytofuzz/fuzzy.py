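"""Mamdani fuzzy inference system for cytokine dose -> growth rate.

Each of the three inputs (IL-2, IL-7, IL-15 dose in ng/mL) and the output
(growth rate, hr^-1) carries two Gaussian membership functions labelled
``low`` and ``high``.  Prediction is the classic Mamdani pipeline:

1. *fuzzify* — evaluate the 2 memberships of each input at the (clamped) dose;
2. *fire rules* — the rule base holds all 2^3 = 8 antecedent combinations;
   a rule's strength is the t-norm (min by default) of its three antecedent
   degrees;
3. *implication/aggregation* — each rule clips its consequent membership at
   its firing strength (min), and the clipped curves are combined pointwise
   by max on a uniform grid over the output universe;
4. *defuzzify* — the centroid sum(y * A(y)) / sum(A(y)) of the aggregate.

The complete rule base guarantees that some rule fires for every in-universe
input, so prediction is total and continuous.  Models serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

LABELS = ("low", "high")


@dataclass
class GaussianMF:
    """Gaussian membership exp(-(x - mean)^2 / (2 sigma^2)); peak 1 at mean."""

    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(under="ignore"):  # far-field degrees flush to 0
            out = np.exp(-((x - self.mean) ** 2) / (2.0 * self.sigma**2))
        return float(out) if out.ndim == 0 else out


def gaussian_membership(x, mf: GaussianMF):
    """Membership degree of ``x`` under ``mf`` (scalar or array)."""
    return mf(x)


@dataclass
class FuzzyVariable:
    """A named variable with universe [lo, hi] and low/high Gaussian MFs."""

    name: str
    lo: float
    hi: float
    low: GaussianMF
    high: GaussianMF

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: universe requires lo < hi")

    def clamp(self, x):
        return np.clip(x, self.lo, self.hi)

    def degrees(self, x) -> np.ndarray:
        """Stacked (…, 2) array of low/high membership degrees."""
        x = self.clamp(np.asarray(x, dtype=float))
        return np.stack([self.low(x), self.high(x)], axis=-1)


@dataclass
class MamdaniFIS:
    """Three-input, one-output Mamdani system with a complete 8-rule base.

    ``rules`` maps each antecedent corner (tuple of 'low'/'high' per input,
    in input order) to a consequent label of the output variable.
    """

    inputs: list[FuzzyVariable]
    output: FuzzyVariable
    rules: dict[tuple[str, str, str], str]
    resolution: int = 201
    and_op: str = "min"  # or "prod"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inputs) != 3:
            raise ValueError("expected exactly 3 input variables")
        corners = {
            (a, b, c) for a in LABELS for b in LABELS for c in LABELS
        }
        if set(self.rules) != corners:
            raise ValueError("rule base must cover all 8 antecedent corners exactly")
        if any(lbl not in LABELS for lbl in self.rules.values()):
            raise ValueError("rule consequents must be 'low' or 'high'")
        if self.resolution < 2:
            raise ValueError("output grid resolution must be >= 2")
        if self.and_op not in ("min", "prod"):
            raise ValueError(f"unknown t-norm {self.and_op!r}")

    # -- parameter vector (for the PSO tuner) -------------------------------

    @property
    def variables(self) -> list[FuzzyVariable]:
        return [*self.inputs, self.output]

    def get_params(self) -> np.ndarray:
        """Flat 16-vector (mean_low, sigma_low, mean_high, sigma_high) x 4."""
        out = []
        for var in self.variables:
            out.extend([var.low.mean, var.low.sigma, var.high.mean, var.high.sigma])
        return np.asarray(out, dtype=float)

    def set_params(self, params) -> None:
        params = np.asarray(params, dtype=float)
        if params.shape != (16,):
            raise ValueError("expected a flat 16-parameter vector")
        for i, var in enumerate(self.variables):
            ml, sl, mh, sh = params[4 * i : 4 * i + 4]
            var.low = GaussianMF(float(ml), float(sl))
            var.high = GaussianMF(float(mh), float(sh))

    # -- inference ----------------------------------------------------------

    def fuzzify(self, dose) -> np.ndarray:
        """Degrees array of shape (..., 3, 2) for doses of shape (..., 3)."""
        dose = np.asarray(dose, dtype=float)
        if np.any(dose < 0):
            raise ValueError("doses must be >= 0")
        return np.stack(
            [var.degrees(dose[..., i]) for i, var in enumerate(self.inputs)],
            axis=-2,
        )

    def _rule_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(8, 3) antecedent label indices and (8,) consequent indices."""
        corners = sorted(self.rules)
        ant = np.array(
            [[LABELS.index(lbl) for lbl in corner] for corner in corners]
        )
        cons = np.array([LABELS.index(self.rules[c]) for c in corners])
        return ant, cons

    def fire_rules(self, degrees: np.ndarray) -> np.ndarray:
        """Firing strengths (..., 8) from a degrees array (..., 3, 2)."""
        ant, _ = self._rule_index()
        per_input = degrees[..., np.arange(3), ant]  # (..., 8, 3)
        if self.and_op == "min":
            return per_input.min(axis=-1)
        return per_input.prod(axis=-1)

    def output_grid(self) -> np.ndarray:
        return np.linspace(self.output.lo, self.output.hi, self.resolution)

    def defuzzify(self, strengths: np.ndarray, resolution: int | None = None):
        """Centroid of the max-aggregated, min-clipped consequent sets."""
        strengths = np.asarray(strengths, dtype=float)
        scalar = strengths.ndim == 1
        strengths = np.atleast_2d(strengths)
        if strengths.shape[-1] != 8:
            raise ValueError("expected 8 firing strengths")
        res = resolution or self.resolution
        y = np.linspace(self.output.lo, self.output.hi, res)
        _, cons = self._rule_index()
        mf_values = np.stack([self.output.low(y), self.output.high(y)])  # (2, R)
        clipped = np.minimum(strengths[:, :, None], mf_values[cons][None, :, :])
        aggregate = clipped.max(axis=1)  # (N, R)
        # trapezoidal end-weights: a plain Riemann sum over-weights the
        # universe edges and costs O(h) centroid accuracy when an MF sits
        # near a bound
        w = np.ones(res)
        w[0] = w[-1] = 0.5
        area = (aggregate * w).sum(axis=1)
        if np.any(area <= 0):
            raise ValueError("no rule fires: aggregated output is empty")
        centroid = (aggregate * (w * y)[None, :]).sum(axis=1) / area
        return float(centroid[0]) if scalar else centroid

    def predict(self, dose):
        """Crisp predicted growth rate(s); doses are clamped to the universes."""
        dose = np.asarray(dose, dtype=float)
        scalar = dose.ndim == 1
        degrees = self.fuzzify(np.atleast_2d(dose))
        strengths = self.fire_rules(degrees)
        out = self.defuzzify(strengths)
        return float(np.atleast_1d(out)[0]) if scalar else np.asarray(out)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def var_dict(v: FuzzyVariable) -> dict:
            return {
                "name": v.name,
                "lo": v.lo,
                "hi": v.hi,
                "low": {"mean": v.low.mean, "sigma": v.low.sigma},
                "high": {"mean": v.high.mean, "sigma": v.high.sigma},
            }

        return {
            "inputs": [var_dict(v) for v in self.inputs],
            "output": var_dict(self.output),
            "rules": [
                {"antecedent": list(corner), "consequent": label}
                for corner, label in sorted(self.rules.items())
            ],
            "resolution": self.resolution,
            "and_op": self.and_op,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MamdaniFIS":
        def make_var(d: dict) -> FuzzyVariable:
            return FuzzyVariable(
                d["name"],
                float(d["lo"]),
                float(d["hi"]),
                GaussianMF(**d["low"]),
                GaussianMF(**d["high"]),
            )

        rules = {
            tuple(rule["antecedent"]): rule["consequent"] for rule in data["rules"]
        }
        return cls(
            inputs=[make_var(d) for d in data["inputs"]],
            output=make_var(data["output"]),
            rules=rules,
            resolution=int(data.get("resolution", 201)),
            and_op=data.get("and_op", "min"),
            metadata=data.get("metadata", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MamdaniFIS":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- free-function views of the pipeline stages -----------------------------


def fuzzify(dose, fis: MamdaniFIS) -> np.ndarray:
    return fis.fuzzify(dose)


def fire_rules(degrees: np.ndarray, fis: MamdaniFIS) -> np.ndarray:
    return fis.fire_rules(degrees)


def defuzzify_centroid(
    strengths, output: FuzzyVariable, resolution: int = 201
):
    """Centroid defuzzification against an explicit output variable."""
    helper = MamdaniFIS(
        inputs=[
            FuzzyVariable(f"x{i}", 0.0, 1.0, GaussianMF(0.0, 0.25), GaussianMF(1.0, 0.25))
            for i in range(3)
        ],
        output=output,
        rules=_default_rules(),
        resolution=resolution,
    )
    return helper.defuzzify(strengths, resolution=resolution)


def _default_rules() -> dict[tuple[str, str, str], str]:
    """Placeholder complete rule base (consequent = majority label)."""
    return {
        (a, b, c): ("high" if (a, b, c).count("high") >= 2 else "low")
        for a in LABELS
        for b in LABELS
        for c in LABELS
    }


def predict(fis: MamdaniFIS, dose):
    return fis.predict(dose)


def init_fis(
    bounds,
    doses,
    rates,
    names: tuple[str, str, str] = ("il2", "il7", "il15"),
    resolution: int = 201,
    and_op: str = "min",
) -> MamdaniFIS:
    """Initial FIS from experiment bounds and training data.

    Input MFs start at the universe edges (low mean = lo, high mean = hi,
    sigma = width/4); the output universe is [0, 1.25 * max observed rate].
    Each of the 8 antecedent corners takes consequent ``high`` when the mean
    response of the training points nearest that corner (in unit-scaled dose
    space) exceeds the overall mean response, else ``low``; a corner with no
    nearest points falls back to an inverse-distance-weighted mean.
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    rates = np.asarray(rates, dtype=float)
    if doses.size == 0 or rates.size == 0:
        raise ValueError("training data must be nonempty")
    if doses.shape != (rates.size, 3):
        raise ValueError("doses must be (n, 3) matching the rates vector")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != 3:
        raise ValueError("expected bounds for exactly 3 inputs")
    for lo, hi in bounds:
        if lo >= hi:
            raise ValueError("degenerate bounds: lo must be < hi")

    def edge_var(name: str, lo: float, hi: float) -> FuzzyVariable:
        sigma = (hi - lo) / 4.0
        return FuzzyVariable(
            name, lo, hi, GaussianMF(lo, sigma), GaussianMF(hi, sigma)
        )

    inputs = [edge_var(name, lo, hi) for name, (lo, hi) in zip(names, bounds)]
    out_hi = 1.25 * float(rates.max())
    if out_hi <= 0:
        out_hi = 1.0  # all-nonpositive rates: arbitrary positive universe
    output = edge_var("growth_rate", 0.0, out_hi)

    # nearest-corner vote in unit-scaled dose space
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    scaled = (np.clip(doses, lo, hi) - lo) / (hi - lo)
    corners = sorted(
        (a, b, c) for a in LABELS for b in LABELS for c in LABELS
    )
    corner_pts = np.array(
        [[LABELS.index(lbl) for lbl in corner] for corner in corners], dtype=float
    )
    dist = np.linalg.norm(scaled[:, None, :] - corner_pts[None, :, :], axis=2)
    nearest = dist.argmin(axis=1)
    overall = rates.mean()
    rules: dict[tuple[str, str, str], str] = {}
    for ci, corner in enumerate(corners):
        mask = nearest == ci
        if mask.any():
            corner_mean = rates[mask].mean()
        else:
            w = 1.0 / (dist[:, ci] + 1e-9)
            corner_mean = float(np.sum(w * rates) / np.sum(w))
        rules[corner] = "high" if corner_mean > overall else "low"
    return MamdaniFIS(
        inputs=inputs, output=output, rules=rules,
        resolution=resolution, and_op=and_op,
    )
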