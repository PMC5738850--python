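"""Parameter sweeps: evaluate a formula over a 1D or 2D grid of one or two
design factors, all other factors held fixed, producing tidy long-format
tables (one record per grid point) suitable for curves and surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from . import formulas
from .errors import ParameterError

__all__ = [
    "SweepSpec",
    "SurfaceSpec",
    "SweepRecord",
    "SweepTable",
    "make_grid",
    "grid_values",
    "run_sweep",
    "run_surface",
    "spec_from_config",
    "spec_to_config",
]

_SCALES = ("linear", "log")


def grid_values(x_min: float, x_max: float, n_points: int, scale: str,
                integer: bool = False) -> np.ndarray:
    """Inclusive grid from ``x_min`` to ``x_max``.

    Endpoints are assigned exactly (no accumulation drift).  Integer
    factors are rounded to the nearest integer and de-duplicated, which may
    shrink the grid.
    """
    if scale not in _SCALES:
        raise ParameterError(f"scale must be one of {_SCALES}, got {scale!r}")
    if not (isinstance(n_points, (int, np.integer)) and n_points >= 2):
        raise ParameterError(f"n_points must be an integer >= 2, got {n_points!r}")
    if not x_min < x_max:
        raise ParameterError(f"require x_min < x_max, got {x_min!r} >= {x_max!r}")
    if scale == "log":
        if x_min <= 0:
            raise ParameterError(
                f"log scale requires x_min > 0, got {x_min!r}")
        values = np.geomspace(x_min, x_max, n_points)
    else:
        values = np.linspace(x_min, x_max, n_points)
    values[0], values[-1] = x_min, x_max
    if integer:
        values = np.unique(np.rint(values)).astype(float)
    return values


def _check_param_cover(formula_id: str, varying: tuple[str, ...],
                       fixed: dict) -> None:
    info = formulas.get_info(formula_id)
    required = set(info.required_params)
    optional = set(info.optional_params)
    for name in varying:
        if name not in required | optional:
            raise ParameterError(
                f"{name!r} is not a parameter of formula {formula_id!r}; "
                f"parameters: {sorted(required | optional)}")
    supplied = set(fixed) | set(varying)
    # goddard2011 accepts m_markers in place of b
    if "m_markers" in supplied:
        supplied = (supplied - {"m_markers"}) | {"b"}
    if supplied != required:
        missing = sorted(required - supplied)
        extra = sorted(supplied - required)
        parts = []
        if missing:
            parts.append(f"missing {missing}")
        if extra:
            parts.append(f"unexpected {extra}")
        raise ParameterError(
            f"fixed parameters plus varying factor(s) must cover exactly the "
            f"required parameters of {formula_id!r}: " + "; ".join(parts))
    overlap = set(fixed) & set(varying)
    if overlap:
        raise ParameterError(
            f"factor(s) {sorted(overlap)} appear both as varying and fixed")


@dataclass(frozen=True)
class SweepSpec:
    """A 1D sweep: vary ``x_param`` over an inclusive grid, evaluate
    ``formula_id`` with the remaining required parameters from ``fixed``."""

    formula_id: str
    x_param: str
    x_min: float
    x_max: float
    fixed: dict = field(default_factory=dict)
    n_points: int = 101
    scale: str = "linear"

    def __post_init__(self):
        _check_param_cover(self.formula_id, (self.x_param,), self.fixed)
        # force early failure on bad bounds/scale
        grid_values(self.x_min, self.x_max, self.n_points, self.scale)

    def x_values(self) -> np.ndarray:
        return grid_values(self.x_min, self.x_max, self.n_points, self.scale,
                           integer=self.x_param in formulas.INTEGER_FIELDS)


@dataclass(frozen=True)
class SurfaceSpec:
    """A 2D sweep over two distinct factors (row-major: x outer, y inner)."""

    formula_id: str
    x_param: str
    x_min: float
    x_max: float
    y_param: str
    y_min: float
    y_max: float
    fixed: dict = field(default_factory=dict)
    x_points: int = 41
    y_points: int = 41
    x_scale: str = "linear"
    y_scale: str = "linear"

    def __post_init__(self):
        if self.x_param == self.y_param:
            raise ParameterError(
                f"the two varying factors must be distinct, both are "
                f"{self.x_param!r}")
        _check_param_cover(self.formula_id, (self.x_param, self.y_param),
                           self.fixed)
        grid_values(self.x_min, self.x_max, self.x_points, self.x_scale)
        grid_values(self.y_min, self.y_max, self.y_points, self.y_scale)

    def x_values(self) -> np.ndarray:
        return grid_values(self.x_min, self.x_max, self.x_points, self.x_scale,
                           integer=self.x_param in formulas.INTEGER_FIELDS)

    def y_values(self) -> np.ndarray:
        return grid_values(self.y_min, self.y_max, self.y_points, self.y_scale,
                           integer=self.y_param in formulas.INTEGER_FIELDS)

    def transposed(self) -> "SurfaceSpec":
        return SurfaceSpec(
            formula_id=self.formula_id, x_param=self.y_param,
            x_min=self.y_min, x_max=self.y_max, y_param=self.x_param,
            y_min=self.x_min, y_max=self.x_max, fixed=dict(self.fixed),
            x_points=self.y_points, y_points=self.x_points,
            x_scale=self.y_scale, y_scale=self.x_scale)


@dataclass(frozen=True)
class SweepRecord:
    """One evaluated grid point."""

    formula_id: str
    x_param: str
    x_value: float
    accuracy: float
    fixed: dict
    y_param: Optional[str] = None
    y_value: Optional[float] = None


@dataclass(frozen=True)
class SweepTable:
    """Ordered evaluated grid (long format; row-major for surfaces)."""

    records: tuple

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 2:
            raise ParameterError("a sweep table needs at least 2 records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SweepRecord]:
        return iter(self.records)

    @property
    def is_surface(self) -> bool:
        return self.records[0].y_param is not None

    def to_dataframe(self):
        """Long-format :class:`pandas.DataFrame` view of the table."""
        import pandas as pd

        cols = {"formula": [r.formula_id for r in self.records],
                "x_param": [r.x_param for r in self.records],
                "x_value": [r.x_value for r in self.records]}
        if self.is_surface:
            cols["y_param"] = [r.y_param for r in self.records]
            cols["y_value"] = [r.y_value for r in self.records]
        cols["accuracy"] = [r.accuracy for r in self.records]
        cols["fixed"] = [dict(r.fixed) for r in self.records]
        return pd.DataFrame(cols)


def make_grid(spec: SweepSpec) -> list[dict]:
    """Fully-specified parameter sets for every grid point, in order.

    Each grid value merged with the fixed parameters must pass the
    formula's own validation; the first offending value aborts the grid.
    """
    points = []
    for x in spec.x_values():
        params = dict(spec.fixed)
        params[spec.x_param] = _coerce(spec.x_param, x)
        try:
            formulas.validate_field(spec.x_param, params[spec.x_param])
        except ParameterError as exc:
            raise ParameterError(
                f"grid value {spec.x_param}={x} is out of domain: {exc}")
        points.append(params)
    return points


def _coerce(name: str, value: float):
    return int(value) if name in formulas.INTEGER_FIELDS else float(value)


def run_sweep(spec: SweepSpec) -> SweepTable:
    """Evaluate the formula at every grid point of a 1D spec.

    A pure function of the spec: identical specs give identical tables.
    Any evaluation error aborts the whole sweep (no partial tables) and
    carries the grid index.
    """
    records = []
    for i, params in enumerate(make_grid(spec)):
        try:
            r = formulas.evaluate(spec.formula_id, params)
        except Exception as exc:
            raise type(exc)(f"sweep aborted at grid index {i} "
                            f"({spec.x_param}={params[spec.x_param]}): {exc}") from exc
        records.append(SweepRecord(
            formula_id=spec.formula_id, x_param=spec.x_param,
            x_value=float(params[spec.x_param]), accuracy=r,
            fixed=dict(spec.fixed)))
    return SweepTable(records=tuple(records))


def run_surface(spec: SurfaceSpec) -> SweepTable:
    """Row-major evaluation over the Cartesian grid of a 2D spec."""
    records = []
    xs, ys = spec.x_values(), spec.y_values()
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            params = dict(spec.fixed)
            params[spec.x_param] = _coerce(spec.x_param, x)
            params[spec.y_param] = _coerce(spec.y_param, y)
            try:
                r = formulas.evaluate(spec.formula_id, params)
            except Exception as exc:
                raise type(exc)(
                    f"surface aborted at grid index ({i}, {j}) "
                    f"({spec.x_param}={params[spec.x_param]}, "
                    f"{spec.y_param}={params[spec.y_param]}): {exc}") from exc
            records.append(SweepRecord(
                formula_id=spec.formula_id, x_param=spec.x_param,
                x_value=float(params[spec.x_param]), y_param=spec.y_param,
                y_value=float(params[spec.y_param]), accuracy=r,
                fixed=dict(spec.fixed)))
    return SweepTable(records=tuple(records))


# ---------------------------------------------------------------------------
# flat key = value config files
# ---------------------------------------------------------------------------

_SWEEP_KEYS = {"formula", "x_param", "x_min", "x_max", "n_points", "scale"}
_SURFACE_KEYS = {"formula", "x_param", "x_min", "x_max", "x_points", "x_scale",
                 "y_param", "y_min", "y_max", "y_points", "y_scale"}


def _parse_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ParameterError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in stripped.split("=", 1))
            if key in out:
                raise ParameterError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = value
    return out


def _parse_number(value: str):
    try:
        f = float(value)
    except ValueError:
        raise ParameterError(f"expected a number, got {value!r}")
    return int(f) if f == int(f) and "e" not in value.lower() and "." not in value else f


def spec_from_config(path: str | Path) -> SweepSpec | SurfaceSpec:
    """Load a :class:`SweepSpec` or :class:`SurfaceSpec` from a flat
    ``key = value`` file (``#`` starts a comment).

    Recognized keys: ``formula``, ``x_param``, ``x_min``, ``x_max``,
    ``n_points``, ``scale`` for curves; surfaces replace ``n_points`` and
    ``scale`` with per-axis ``x_points/x_scale/y_points/y_scale`` and add
    ``y_param/y_min/y_max``.  ``fixed.<name> = value`` sets a fixed
    parameter.  The presence of ``y_param`` selects the surface form.
    """
    raw = _parse_config(path)
    fixed = {}
    scalar: dict[str, str] = {}
    for key, value in raw.items():
        if key.startswith("fixed."):
            fixed[key[len("fixed."):]] = _parse_number(value)
        else:
            scalar[key] = value
    is_surface = "y_param" in scalar
    allowed = _SURFACE_KEYS if is_surface else _SWEEP_KEYS
    unknown = set(scalar) - allowed
    if unknown:
        raise ParameterError(
            f"{path}: unknown config key(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)} plus fixed.<param>")
    for req in ("formula", "x_param", "x_min", "x_max"):
        if req not in scalar:
            raise ParameterError(f"{path}: missing required key {req!r}")
    if is_surface:
        for req in ("y_min", "y_max"):
            if req not in scalar:
                raise ParameterError(f"{path}: missing required key {req!r}")
        return SurfaceSpec(
            formula_id=scalar["formula"],
            x_param=scalar["x_param"],
            x_min=float(scalar["x_min"]), x_max=float(scalar["x_max"]),
            y_param=scalar["y_param"],
            y_min=float(scalar["y_min"]), y_max=float(scalar["y_max"]),
            fixed=fixed,
            x_points=int(scalar.get("x_points", 41)),
            y_points=int(scalar.get("y_points", 41)),
            x_scale=scalar.get("x_scale", "linear"),
            y_scale=scalar.get("y_scale", "linear"))
    return SweepSpec(
        formula_id=scalar["formula"],
        x_param=scalar["x_param"],
        x_min=float(scalar["x_min"]), x_max=float(scalar["x_max"]),
        fixed=fixed,
        n_points=int(scalar.get("n_points", 101)),
        scale=scalar.get("scale", "linear"))


def spec_to_config(spec: SweepSpec | SurfaceSpec, path: str | Path) -> None:
    """Write a spec back to the flat config dialect (round-trips with
    :func:`spec_from_config`)."""
    lines = [f"formula = {spec.formula_id}",
             f"x_param = {spec.x_param}",
             f"x_min = {spec.x_min!r}",
             f"x_max = {spec.x_max!r}"]
    if isinstance(spec, SurfaceSpec):
        lines += [f"x_points = {spec.x_points}",
                  f"x_scale = {spec.x_scale}",
                  f"y_param = {spec.y_param}",
                  f"y_min = {spec.y_min!r}",
                  f"y_max = {spec.y_max!r}",
                  f"y_points = {spec.y_points}",
                  f"y_scale = {spec.y_scale}"]
    else:
        lines += [f"n_points = {spec.n_points}",
                  f"scale = {spec.scale}"]
    for name in sorted(spec.fixed):
        lines.append(f"fixed.{name} = {spec.fixed[name]!r}")
    Path(path).write_text("\n".join(lines) + "\n")
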