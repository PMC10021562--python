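"""Construction and evaluation of effects-coded choice-experiment designs.

A discrete choice experiment (DCE) instrument presents respondents with a
sequence of *tasks*, each offering two unlabelled partnership profiles plus a
"neither" opt-out.  Profiles are combinations of attribute levels (condom use,
money, payment timing, relationship length, partner age).  This module builds
such instruments: it enumerates the candidate profile space, effects-codes
profiles into design columns, evaluates a design's local D-error at prior
coefficients, and searches for a D-efficient design by coordinate exchange.

Effects coding: an attribute with L levels contributes L-1 columns; level
k < L maps to the k-th unit indicator, the reference level (last listed) maps
to -1 in every column, so level utilities sum to zero within an attribute.
Continuous attributes contribute their numeric value as a single column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AttributeSpec",
    "ChoiceDesign",
    "SingularDesignError",
    "load_attributes",
    "default_attributes",
    "enumerate_full_factorial",
    "effects_code",
    "code_profiles",
    "design_columns",
    "coded_design_array",
    "d_error",
    "search_efficient_design",
]

OPT_OUT_COLUMN = "opt_out"

_CONFIG_DIR = Path(__file__).parent / "configs"


class SingularDesignError(ValueError):
    """Raised when every candidate design has a singular information matrix."""


def _slug(label: str) -> str:
    out = "".join(ch if ch.isalnum() else "_" for ch in label.lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


@dataclass(frozen=True)
class AttributeSpec:
    """One DCE attribute: its levels and how it enters the utility function.

    Parameters
    ----------
    name : attribute label, e.g. ``"money"``.
    levels : ordered level labels; the *last* level is the effects-coding
        reference.
    coding : ``"effects"`` (categorical, L-1 contrast columns) or
        ``"continuous"`` (one column holding ``numeric_values``).
    numeric_values : per-level numbers, required iff ``coding="continuous"``
        (GMD for the money attribute).
    codes : optional short per-level identifiers used for coded column names;
        defaults to slugs of the level labels.
    units : free-text unit annotation.
    """

    name: str
    levels: tuple[str, ...]
    coding: str = "effects"
    numeric_values: tuple[float, ...] | None = None
    codes: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate level labels")
        if self.coding not in ("effects", "continuous"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding == "continuous":
            if self.numeric_values is None or len(self.numeric_values) != len(self.levels):
                raise ValueError(
                    f"continuous attribute {self.name!r} requires one numeric value per level"
                )
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.numeric_values is not None:
            object.__setattr__(self, "numeric_values", tuple(float(v) for v in self.numeric_values))
        if self.codes is not None:
            if len(self.codes) != len(self.levels):
                raise ValueError(f"attribute {self.name!r}: codes must match levels")
            object.__setattr__(self, "codes", tuple(self.codes))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_columns(self) -> int:
        return 1 if self.coding == "continuous" else self.n_levels - 1

    @property
    def level_codes(self) -> tuple[str, ...]:
        return self.codes if self.codes is not None else tuple(_slug(lv) for lv in self.levels)

    def column_names(self) -> list[str]:
        if self.coding == "continuous":
            return [self.name]
        if self.codes is not None:
            return list(self.codes[:-1])
        return [f"{self.name}__{_slug(lv)}" for lv in self.levels[:-1]]

    def code_level(self, level_index: int) -> np.ndarray:
        """Coded row segment for one level of this attribute."""
        if not 0 <= level_index < self.n_levels:
            raise ValueError(
                f"level index {level_index} out of range for attribute {self.name!r}"
            )
        if self.coding == "continuous":
            return np.array([self.numeric_values[level_index]], dtype=float)
        row = np.zeros(self.n_levels - 1)
        if level_index == self.n_levels - 1:  # reference level
            row[:] = -1.0
        else:
            row[level_index] = 1.0
        return row


def load_attributes(path: str | Path) -> list[AttributeSpec]:
    """Read an attribute specification from a YAML/JSON config file.

    Expected layout::

        attributes:
          - name: money
            levels: ["No money", "500 dalasi", ...]
            coding: effects          # or continuous
            numeric_values: [0, 500, ...]   # continuous only
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return attributes_from_dict(doc)


def attributes_from_dict(doc: dict) -> list[AttributeSpec]:
    specs = []
    for entry in doc["attributes"]:
        specs.append(
            AttributeSpec(
                name=entry["name"],
                levels=tuple(entry["levels"]),
                coding=entry.get("coding", "effects"),
                numeric_values=tuple(entry["numeric_values"]) if "numeric_values" in entry else None,
                codes=tuple(entry["codes"]) if "codes" in entry else None,
                units=entry.get("units", ""),
            )
        )
    return specs


def default_attributes() -> list[AttributeSpec]:
    """The five-attribute tourist-partnership instrument shipped with the package."""
    return load_attributes(_CONFIG_DIR / "attributes.yaml")


def design_columns(attributes: list[AttributeSpec], include_opt_out: bool = True) -> list[str]:
    """Names of the coded columns, in design order (attributes then opt-out)."""
    cols: list[str] = []
    for attr in attributes:
        cols.extend(attr.column_names())
    if include_opt_out:
        cols.append(OPT_OUT_COLUMN)
    return cols


def enumerate_full_factorial(attributes: list[AttributeSpec]) -> np.ndarray:
    """All level-index combinations, one row per profile.

    Returns an integer array of shape ``(prod(n_levels), n_attributes)``.
    """
    if not attributes:
        raise ValueError("attribute list is empty")
    grids = np.meshgrid(*[np.arange(a.n_levels) for a in attributes], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def effects_code(profile, attributes: list[AttributeSpec]) -> np.ndarray:
    """Code one profile (sequence of level indices) into its design row.

    The row covers only attribute columns; the opt-out constant is appended
    at the design level.
    """
    profile = np.asarray(profile, dtype=int)
    if profile.shape != (len(attributes),):
        raise ValueError("profile length must equal number of attributes")
    return np.concatenate(
        [attr.code_level(int(ix)) for attr, ix in zip(attributes, profile)]
    )


def code_profiles(profiles: np.ndarray, attributes: list[AttributeSpec]) -> np.ndarray:
    """Vectorised :func:`effects_code` over a profile array (n_profiles, n_attrs)."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=int))
    return np.stack([effects_code(p, attributes) for p in profiles])


@dataclass
class ChoiceDesign:
    """A complete DCE instrument.

    ``profiles[t, a]`` holds the level-index assignment for non-opt-out
    alternative ``a`` of task ``t``.  When ``has_opt_out`` the coded design
    appends one extra alternative per task whose attribute columns are all
    zero and whose opt-out constant is one.
    """

    attributes: list[AttributeSpec]
    profiles: np.ndarray  # (n_tasks, n_profile_alts, n_attributes) int
    has_opt_out: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=int)
        if self.profiles.ndim != 3:
            raise ValueError("profiles must have shape (n_tasks, n_alternatives, n_attributes)")
        if self.profiles.shape[2] != len(self.attributes):
            raise ValueError("profile width must equal number of attributes")
        for k, attr in enumerate(self.attributes):
            col = self.profiles[:, :, k]
            if col.min() < 0 or col.max() >= attr.n_levels:
                raise ValueError(f"level index out of range for attribute {attr.name!r}")

    @property
    def n_tasks(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_profile_alternatives(self) -> int:
        return self.profiles.shape[1]

    @property
    def n_alternatives(self) -> int:
        return self.n_profile_alternatives + int(self.has_opt_out)

    def columns(self) -> list[str]:
        return design_columns(self.attributes, include_opt_out=self.has_opt_out)

    def coded_array(self) -> np.ndarray:
        """Coded design, shape ``(n_tasks, n_alternatives, n_columns)``."""
        return coded_design_array(self)

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "coding": a.coding,
                    **({"numeric_values": list(a.numeric_values)} if a.numeric_values else {}),
                    **({"codes": list(a.codes)} if a.codes else {}),
                    **({"units": a.units} if a.units else {}),
                }
                for a in self.attributes
            ],
            "profiles": self.profiles.tolist(),
            "has_opt_out": self.has_opt_out,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "ChoiceDesign":
        return cls(
            attributes=attributes_from_dict(doc),
            profiles=np.asarray(doc["profiles"], dtype=int),
            has_opt_out=doc.get("has_opt_out", True),
            metadata=doc.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChoiceDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def questionnaire(self):
        """Human-readable questionnaire: one row per task x alternative with level labels."""
        import pandas as pd

        rows = []
        for t in range(self.n_tasks):
            for a in range(self.n_profile_alternatives):
                row = {"task": t + 1, "alternative": f"Option {chr(ord('A') + a)}"}
                for k, attr in enumerate(self.attributes):
                    row[attr.name] = attr.levels[self.profiles[t, a, k]]
                rows.append(row)
            if self.has_opt_out:
                row = {"task": t + 1, "alternative": "Neither"}
                for attr in self.attributes:
                    row[attr.name] = ""
                rows.append(row)
        return pd.DataFrame(rows)


def coded_design_array(design: ChoiceDesign) -> np.ndarray:
    n_attr_cols = sum(a.n_columns for a in design.attributes)
    n_cols = n_attr_cols + int(design.has_opt_out)
    X = np.zeros((design.n_tasks, design.n_alternatives, n_cols))
    for t in range(design.n_tasks):
        for a in range(design.n_profile_alternatives):
            X[t, a, :n_attr_cols] = effects_code(design.profiles[t, a], design.attributes)
    if design.has_opt_out:
        X[:, -1, -1] = 1.0  # zeros elsewhere: the opt-out carries no profile
    return X


def _information_matrix(X: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """MNL Fisher information of a coded design at the prior coefficients.

    ``X`` has shape (n_tasks, J, K).  For each task the contribution is
    ``X' (diag(P) - P P') X`` with P the logit probabilities at the priors.
    """
    U = X @ priors  # (T, J)
    U = U - U.max(axis=1, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=1, keepdims=True)
    xbar = np.einsum("tj,tjk->tk", P, X)
    Xc = X - xbar[:, None, :]
    return np.einsum("tj,tjk,tjl->kl", P, Xc, Xc)


def d_error(design: ChoiceDesign, priors) -> float:
    """Local D-error ``det(I(beta))**(-1/K)`` of a design at point priors.

    Returns ``inf`` when the information matrix is singular (the design does
    not identify all K parameters), rather than raising.
    """
    X = design.coded_array()
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (X.shape[2],):
        raise ValueError(
            f"prior length {priors.shape} does not match coded column count {X.shape[2]}"
        )
    if design.n_tasks < 1:
        raise ValueError("design must contain at least one task")
    info = _information_matrix(X, priors)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    K = X.shape[2]
    return float(np.exp(-logdet / K))


def _d_error_from_profiles(profile_ix: np.ndarray, coded_candidates: np.ndarray,
                           n_attr_cols: int, has_opt_out: bool, priors: np.ndarray) -> float:
    """D-error for a (n_tasks, n_alts) index array into the candidate profile set."""
    T, A = profile_ix.shape
    J = A + int(has_opt_out)
    K = n_attr_cols + int(has_opt_out)
    X = np.zeros((T, J, K))
    X[:, :A, :n_attr_cols] = coded_candidates[profile_ix]
    if has_opt_out:
        X[:, -1, -1] = 1.0
    info = _information_matrix(X, priors)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    return float(np.exp(-logdet / K))


def search_efficient_design(
    attributes: list[AttributeSpec],
    priors,
    n_tasks: int,
    n_alternatives: int = 2,
    seed: int = 0,
    n_restarts: int = 3,
    max_sweeps: int = 20,
    has_opt_out: bool = True,
) -> ChoiceDesign:
    """Coordinate-exchange search for a locally D-efficient design.

    From a random start, every (task, alternative) slot is visited in turn and
    its profile swapped for the candidate (from the full factorial) that most
    reduces the D-error; a swap is accepted only on strict decrease, so the
    trajectory is monotone non-increasing.  The best design over ``n_restarts``
    random starts is returned.  Deterministic given ``seed``.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = enumerate_full_factorial(attributes)
    coded_candidates = code_profiles(candidates, attributes)
    n_attr_cols = coded_candidates.shape[1]
    priors = np.asarray(priors, dtype=float)
    n_cand = len(candidates)

    best_ix = None
    best_err = float("inf")
    for _ in range(n_restarts):
        ix = rng.integers(0, n_cand, size=(n_tasks, n_alternatives))
        err = _d_error_from_profiles(ix, coded_candidates, n_attr_cols, has_opt_out, priors)
        for _ in range(max_sweeps):
            improved = False
            for t in range(n_tasks):
                for a in range(n_alternatives):
                    current = ix[t, a]
                    best_local, best_local_err = current, err
                    for c in range(n_cand):
                        if c == current:
                            continue
                        ix[t, a] = c
                        e = _d_error_from_profiles(
                            ix, coded_candidates, n_attr_cols, has_opt_out, priors
                        )
                        if e < best_local_err:
                            best_local, best_local_err = c, e
                    ix[t, a] = best_local
                    if best_local_err < err:
                        err = best_local_err
                        improved = True
            if not improved:
                break
        if err < best_err:
            best_err = err
            best_ix = ix.copy()

    if best_ix is None or not np.isfinite(best_err):
        raise SingularDesignError(
            "every design visited during the search had a singular information matrix"
        )
    design = ChoiceDesign(
        attributes=attributes,
        profiles=candidates[best_ix],
        has_opt_out=has_opt_out,
        metadata={
            "d_error": best_err,
            "seed": seed,
            "n_restarts": n_restarts,
            "algorithm": "coordinate-exchange",
        },
    )
    return design


def random_balanced_design(
    attributes: list[AttributeSpec],
    n_tasks: int,
    n_alternatives: int = 2,
    seed: int = 0,
    has_opt_out: bool = True,
) -> ChoiceDesign:
    """Seeded random design with approximately balanced level frequencies.

    Stands in for an orthogonal pilot array when no orthogonal array of the
    requested size exists; flagged as such in the metadata.  Each attribute's
    levels are cycled through a shuffled order across the task x alternative
    slots, so level counts differ by at most one.
    """
    rng = np.random.default_rng(seed)
    n_slots = n_tasks * n_alternatives
    cols = []
    for attr in attributes:
        reps = np.tile(np.arange(attr.n_levels), n_slots // attr.n_levels + 1)[:n_slots]
        rng.shuffle(reps)
        cols.append(reps)
    profiles = np.stack(cols, axis=1).reshape(n_tasks, n_alternatives, len(attributes))
    return ChoiceDesign(
        attributes=attributes,
        profiles=profiles,
        has_opt_out=has_opt_out,
        metadata={"seed": seed, "algorithm": "random-balanced (orthogonal-array stand-in)"},
    )
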