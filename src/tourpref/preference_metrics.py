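"""Willingness-to-accept (WTA) analysis of fitted choice models.

WTA for an attribute contrast is the money transfer that exactly offsets the
utility change: ``WTA = -(delta_beta) / beta_money`` with the money coefficient
(per GMD) as denominator.  A disliked contrast (negative utility change) under
a positive money coefficient therefore yields a positive compensation.

Interval estimates use the Krinsky-Robb procedure: draw coefficient vectors
from the estimator's asymptotic multivariate normal and take percentile bounds
of the simulated ratio distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .choice_models import EstimationResult
from .experimental_design import AttributeSpec

__all__ = ["WTAEstimate", "Contrast", "wta", "krinsky_robb_ci", "level_contrast", "wta_table"]

#: |beta_money| per GMD below which the ratio is declared unstable
MONEY_FLOOR = 1e-12


@dataclass(frozen=True)
class Contrast:
    """A named linear combination of coefficients, ``sum_k w_k beta_k``.

    ``weights`` maps coefficient names to weights.  For a from->to level move
    of an effects-coded attribute use :func:`level_contrast`, which is
    invariant to the choice of reference level.
    """

    name: str
    weights: dict[str, float]

    def value(self, names: list[str], estimates: np.ndarray) -> float:
        return float(self.vector(names) @ estimates)

    def vector(self, names: list[str]) -> np.ndarray:
        v = np.zeros(len(names))
        index = {n: i for i, n in enumerate(names)}
        for n, w in self.weights.items():
            if n not in index:
                raise KeyError(f"contrast references unknown coefficient {n!r}")
            v[index[n]] = w
        return v


def level_contrast(attribute: AttributeSpec, from_level: str, to_level: str) -> Contrast:
    """Utility change from moving ``from_level`` -> ``to_level`` of one attribute.

    Expressed through the attribute's coded columns, so the implied utility of
    the reference level (minus the sum of the others) is handled and the
    result does not depend on which level was chosen as reference.
    """
    if attribute.coding != "effects":
        raise ValueError("level_contrast applies to effects-coded attributes")
    names = attribute.column_names()

    def level_weights(label: str) -> dict[str, float]:
        labels = list(attribute.levels)
        codes = list(attribute.level_codes)
        key = label if label in labels else (label if label in codes else None)
        if key is None:
            raise KeyError(f"unknown level {label!r} for attribute {attribute.name!r}")
        ix = labels.index(label) if label in labels else codes.index(label)
        if ix == attribute.n_levels - 1:  # reference: -sum of coded columns
            return {n: -1.0 for n in names}
        return {names[ix]: 1.0}

    w_from = level_weights(from_level)
    w_to = level_weights(to_level)
    weights: dict[str, float] = {}
    for n in set(w_from) | set(w_to):
        weights[n] = w_to.get(n, 0.0) - w_from.get(n, 0.0)
    return Contrast(name=f"{attribute.name}: {from_level} -> {to_level}", weights=weights)


@dataclass
class WTAEstimate:
    """Money-denominated compensation for an attribute contrast, in GMD."""

    contrast: str
    point: float
    ci_lower: float
    ci_upper: float
    level: float
    n_sim_draws: int
    seed: int
    unstable: bool = False
    units: str = "GMD"
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "level": self.level,
            "n_sim_draws": self.n_sim_draws,
            "seed": self.seed,
            "unstable": self.unstable,
            "units": self.units,
        }


def _money_coefficient(result: EstimationResult, money_key: str) -> tuple[int, float]:
    if any(n.startswith(f"{money_key}_") and n != money_key for n in result.names) and (
        money_key not in result.names
    ):
        raise ValueError(
            "WTA requires a continuous (per-GMD) money coefficient; this model "
            f"effects-codes money ({money_key!r} not among its coefficients)"
        )
    if money_key not in result.names:
        raise ValueError(f"money coefficient {money_key!r} not present in the fitted model")
    ix = result.names.index(money_key)
    return ix, float(result.estimates[ix])


def krinsky_robb_ci(
    result: EstimationResult,
    contrast: Contrast,
    money_key: str = "money",
    n_sim_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    money_scale: float | None = None,
) -> tuple[float, float]:
    """Percentile interval for the WTA ratio over asymptotic-normal draws.

    Deterministic given ``seed``.  A non-PSD covariance is repaired by
    clipping negative eigenvalues to zero (with a warning in the metadata of
    callers that care); draws with a money coefficient inside the numeric
    floor are counted but excluded from the percentile computation.
    """
    scale = _resolve_money_scale(result, money_scale)
    money_ix, _ = _money_coefficient(result, money_key)
    cvec = contrast.vector(result.names)
    vcov = np.asarray(result.vcov, dtype=float)
    # symmetrise and clip to PSD if needed
    vcov = (vcov + vcov.T) / 2
    w, V = np.linalg.eigh(vcov)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        import warnings

        warnings.warn("vcov not positive semidefinite; clipping negative eigenvalues")
    w = np.clip(w, 0, None)
    root = V * np.sqrt(w)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sim_draws, len(result.names)))
    draws = result.estimates + z @ root.T
    num = draws @ cvec
    den = draws[:, money_ix] / scale
    ok = np.abs(den) > MONEY_FLOOR
    ratios = -num[ok] / den[ok]
    if not ok.any():
        return (float("nan"), float("nan"))
    alpha = (1 - level) / 2
    return (float(np.quantile(ratios, alpha)), float(np.quantile(ratios, 1 - alpha)))


def _resolve_money_scale(result: EstimationResult, money_scale: float | None) -> float:
    """GMD per unit of the money design column (1 if the column is raw GMD)."""
    if money_scale is not None:
        return money_scale
    return float(result.metadata.get("money_scale", 1.0))


def wta(
    result: EstimationResult,
    contrast: Contrast,
    money_key: str = "money",
    n_sim_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    money_scale: float | None = None,
) -> WTAEstimate:
    """Point and interval WTA for a contrast, in GMD.

    ``point = -(delta utility) / beta_money``, with ``beta_money`` converted
    to the per-GMD scale via ``money_scale`` (GMD per design-column unit,
    taken from the result metadata when the money column was rescaled for
    optimiser conditioning).
    """
    scale = _resolve_money_scale(result, money_scale)
    money_ix, b_money = _money_coefficient(result, money_key)
    b_money_per_gmd = b_money / scale
    dbeta = contrast.value(result.names, result.estimates)
    unstable = abs(b_money_per_gmd) <= MONEY_FLOOR
    point = 0.0 if dbeta == 0 else (float("nan") if unstable else -dbeta / b_money_per_gmd)
    lo, hi = krinsky_robb_ci(
        result, contrast, money_key=money_key, n_sim_draws=n_sim_draws,
        seed=seed, level=level, money_scale=scale,
    )
    if np.isfinite(point):
        lo, hi = min(lo, point), max(hi, point)
    return WTAEstimate(
        contrast=contrast.name,
        point=point,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        n_sim_draws=n_sim_draws,
        seed=seed,
        unstable=bool(unstable),
    )


def wta_table(
    result: EstimationResult,
    contrasts: list[Contrast],
    money_key: str = "money",
    n_sim_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, WTAEstimate]:
    """WTA for several contrasts, keyed by contrast name."""
    return {
        c.name: wta(result, c, money_key=money_key, n_sim_draws=n_sim_draws, seed=seed, level=level)
        for c in contrasts
    }


def wta_report(estimates: dict[str, WTAEstimate], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in estimates.items()}, indent=2)
    )
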