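"""Deterministic formulas for the expected accuracy of genomic prediction.

Eight closed-form expressions map population-genetic design factors
(training-set size ``N``, heritability ``h2``, independent chromosome
segments ``Me``, effective population size ``Ne``, marker number ``M``,
marker-captured variance fraction ``b``, and their two-population
analogues) to the expected correlation ``r`` between true and predicted
genomic values.  Seven formulas address a single training population; the
eighth combines two training populations to predict accuracy in a third.

All functions are pure, validate their inputs eagerly, and raise
:class:`~gpasim.errors.ParameterError` naming the offending field before
any arithmetic runs.  A registry (:data:`REGISTRY`) exposes the eight
formulas for uniform dispatch via :func:`evaluate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import FormulaLookupError, LinearAlgebraError, NumericalDomainError, ParameterError

__all__ = [
    "WithinPopParams",
    "MultiPopParams",
    "GoddardTerms",
    "FormulaInfo",
    "REGISTRY",
    "FORMULA_IDS",
    "daetwyler",
    "goddard_terms",
    "goddard2009",
    "goddard2011",
    "rabier",
    "rabier_eterm",
    "deloscampos",
    "karaman",
    "wientjes",
    "evaluate",
    "list_formulas",
    "required_params",
]

# Round-off tolerance: radicands in [-_CLAMP_TOL, 0) are treated as 0;
# anything more negative is a genuine domain violation and raises.
_CLAMP_TOL = 1e-12

# Reciprocal-condition floor for the 2x2 multi-population solve.
_RCOND_MIN = 1e-12


# ---------------------------------------------------------------------------
# field validation
# ---------------------------------------------------------------------------

def _check_count(name: str, value) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ParameterError(f"{name} must be a positive integer, got {value!r}")
    if not math.isfinite(f) or f < 1 or f != int(f):
        raise ParameterError(f"{name} must be a positive integer, got {value!r}")
    return int(f)


def _check_real(name: str, value, lo: float, hi: float,
                lo_open: bool = False, hi_open: bool = False) -> float:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ParameterError(f"{name} must be a real number, got {value!r}")
    if not math.isfinite(f):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    lo_ok = f > lo if lo_open else f >= lo
    hi_ok = f < hi if hi_open else f <= hi
    if not (lo_ok and hi_ok):
        lb = "(" if lo_open else "["
        rb = ")" if hi_open else "]"
        raise ParameterError(
            f"{name}={f} outside valid domain {lb}{_fmt(lo)}, {_fmt(hi)}{rb}")
    return f


def _fmt(x: float) -> str:
    return "inf" if math.isinf(x) else repr(x)


_INF = math.inf

#: name -> validator; the single source of truth for parameter domains.
FIELD_VALIDATORS: dict[str, Callable[[object], float]] = {
    "n_train": lambda v: _check_count("n_train", v),
    "h2": lambda v: _check_real("h2", v, 0.0, 1.0, lo_open=True),
    "h2_m": lambda v: _check_real("h2_m", v, 0.0, 1.0, lo_open=True),
    "me": lambda v: _check_real("me", v, 0.0, _INF, lo_open=True),
    "ne": lambda v: _check_real("ne", v, 0.5, _INF, lo_open=True),
    "m_markers": lambda v: _check_count("m_markers", v),
    "b": lambda v: _check_real("b", v, 0.0, 1.0),
    "eterm": lambda v: _check_real("eterm", v, 0.0, _INF),
    "n_a": lambda v: _check_count("n_a", v),
    "n_b": lambda v: _check_count("n_b", v),
    "h2_a": lambda v: _check_real("h2_a", v, 0.0, 1.0, lo_open=True),
    "h2_b": lambda v: _check_real("h2_b", v, 0.0, 1.0, lo_open=True),
    "me_ac": lambda v: _check_real("me_ac", v, 0.0, _INF, lo_open=True),
    "me_bc": lambda v: _check_real("me_bc", v, 0.0, _INF, lo_open=True),
    "r_g_ac": lambda v: _check_real("r_g_ac", v, -1.0, 1.0),
    "r_g_bc": lambda v: _check_real("r_g_bc", v, -1.0, 1.0),
    "r_g_ab": lambda v: _check_real("r_g_ab", v, -1.0, 1.0),
    "b_ac": lambda v: _check_real("b_ac", v, 0.0, 1.0),
    "b_bc": lambda v: _check_real("b_bc", v, 0.0, 1.0),
}

#: integer-valued design factors (relevant to sweep gridding).
INTEGER_FIELDS = frozenset({"n_train", "m_markers", "n_a", "n_b"})


def validate_field(name: str, value):
    """Validate a single named parameter; return the coerced value."""
    try:
        validator = FIELD_VALIDATORS[name]
    except KeyError:
        raise ParameterError(
            f"unknown parameter {name!r}; known: {sorted(FIELD_VALIDATORS)}")
    return validator(value)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WithinPopParams:
    """Design factors for the seven single-population formulas.

    Only the fields a given formula requires need be supplied; every
    supplied field is validated against its domain at construction time.
    """

    n_train: Optional[int] = None
    h2: Optional[float] = None
    h2_m: Optional[float] = None
    me: Optional[float] = None
    ne: Optional[float] = None
    m_markers: Optional[int] = None
    b: Optional[float] = None
    eterm: Optional[float] = None

    def __post_init__(self):
        for name in ("n_train", "h2", "h2_m", "me", "ne",
                     "m_markers", "b", "eterm"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, validate_field(name, value))

    def require(self, *names: str):
        """Return the named fields, raising if any is absent."""
        out = []
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ParameterError(f"required parameter {name!r} is missing")
            out.append(value)
        return out


@dataclass(frozen=True)
class MultiPopParams:
    """Design factors for the two-training-population formula.

    All fields are mandatory.  ``b_ac``/``b_bc`` are the *square roots* of
    the fractions of genetic variance in the predicted population captured
    by the respective marker panels.
    """

    n_a: int
    n_b: int
    h2_a: float
    h2_b: float
    me_ac: float
    me_bc: float
    r_g_ac: float
    r_g_bc: float
    r_g_ab: float
    b_ac: float
    b_bc: float

    def __post_init__(self):
        for name in ("n_a", "n_b", "h2_a", "h2_b", "me_ac", "me_bc",
                     "r_g_ac", "r_g_bc", "r_g_ab", "b_ac", "b_bc"):
            object.__setattr__(self, name, validate_field(name, getattr(self, name)))

    def swapped(self) -> "MultiPopParams":
        """Exchange all A-labels with all B-labels (a formula symmetry)."""
        return MultiPopParams(
            n_a=self.n_b, n_b=self.n_a, h2_a=self.h2_b, h2_b=self.h2_a,
            me_ac=self.me_bc, me_bc=self.me_ac, r_g_ac=self.r_g_bc,
            r_g_bc=self.r_g_ac, r_g_ab=self.r_g_ab,
            b_ac=self.b_bc, b_bc=self.b_ac)


@dataclass(frozen=True)
class GoddardTerms:
    """Intermediate quantities of the random-marker / complete-LD formula:
    ``lambda_ = Me / (h2 * ln(2 Ne))`` and
    ``alpha = 1 + 2 * Me / (N * h2 * ln(2 Ne))``."""

    lambda_: float
    alpha: float


# ---------------------------------------------------------------------------
# the eight formulas
# ---------------------------------------------------------------------------

def _sqrt_clamped(radicand: float, context: str) -> float:
    if radicand < 0.0:
        if radicand < -_CLAMP_TOL:
            raise NumericalDomainError(
                f"{context}: radicand {radicand} below -{_CLAMP_TOL}")
        radicand = 0.0
    return math.sqrt(radicand)


def daetwyler(n_train, h2, me) -> float:
    """Fixed-marker, complete-LD accuracy: ``sqrt(N h2 / (N h2 + Me))``.

    Assumes independent QTL, unit residual variance with genetic plus
    residual variance equal to one, and perfect marker-QTL LD.
    """
    n = validate_field("n_train", n_train)
    h2 = validate_field("h2", h2)
    me = validate_field("me", me)
    nh2 = n * h2
    return math.sqrt(nh2 / (nh2 + me))


def goddard_terms(n_train, h2, me, ne) -> GoddardTerms:
    """Intermediate ``lambda`` and ``alpha`` terms of :func:`goddard2009`."""
    n = validate_field("n_train", n_train)
    h2 = validate_field("h2", h2)
    me = validate_field("me", me)
    ne = validate_field("ne", ne)
    log2ne = math.log(2.0 * ne)  # ne > 0.5 guarantees positivity
    lambda_ = me / (h2 * log2ne)
    alpha = 1.0 + 2.0 * me / (n * h2 * log2ne)
    return GoddardTerms(lambda_=lambda_, alpha=alpha)


def goddard2009(n_train, h2, me, ne) -> float:
    """Random-marker, complete-LD accuracy.

    The published expression is
    ``sqrt(1 - lambda/(2 N sqrt(alpha)) * ln((1+alpha+2 sqrt(alpha)) /
    (1+alpha-2 sqrt(alpha))))``.  Because ``1+alpha±2 sqrt(alpha) =
    (sqrt(alpha)±1)**2``, the log term is evaluated here as
    ``2 ln((sqrt(alpha)+1)/(sqrt(alpha)-1))``, which avoids catastrophic
    cancellation as ``alpha -> 1`` (large ``N``).  For large ``alpha``
    (small accuracy) the radicand itself cancels against 1, so it is
    instead summed from its exact power series in ``u = 1/alpha``:
    with ``radicand = 1 - ((1-u) / sqrt(u)) artanh(sqrt(u))`` this equals
    ``sum_{k>=1} 2 u^k / ((2k-1)(2k+1))``, keeping full relative accuracy
    over the whole domain.
    """
    n = validate_field("n_train", n_train)
    h2 = validate_field("h2", h2)
    me = validate_field("me", me)
    ne = validate_field("ne", ne)
    theta = me / (n * h2 * math.log(2.0 * ne))  # = lambda / N = (alpha-1)/2
    u = 1.0 / (1.0 + 2.0 * theta)               # = 1/alpha, in (0, 1)
    if u <= 0.5:
        power = u
        radicand = 0.0
        for k in range(1, 60):  # geometric tail <= 2^-k: 60 terms suffice
            term = 2.0 * power / ((2 * k - 1) * (2 * k + 1))
            radicand += term
            if term <= radicand * 1e-17:
                break
            power *= u
    else:
        sqrt_a = math.sqrt(1.0 + 2.0 * theta)
        sqrt_a_m1 = 2.0 * theta / (sqrt_a + 1.0)  # sqrt(alpha)-1, no cancellation
        log_term = 2.0 * math.log1p(2.0 / sqrt_a_m1)
        radicand = 1.0 - theta / (2.0 * sqrt_a) * log_term
    return _sqrt_clamped(radicand, "goddard2009")


def goddard2011(n_train, h2, me, b=None, m_markers=None) -> float:
    """Incomplete-LD accuracy: ``sqrt(b * (N b h2 / Me) / (1 + N b h2 / Me))``.

    ``b`` is the fraction of genetic variance captured by the marker panel.
    Supply either ``b`` directly or the marker count ``m_markers``, in
    which case ``b = M / (M + Me)``; supplying both is ambiguous and an
    error.  With ``b = 1`` this reduces exactly to :func:`daetwyler`.
    """
    n = validate_field("n_train", n_train)
    h2 = validate_field("h2", h2)
    me = validate_field("me", me)
    if b is not None and m_markers is not None:
        raise ParameterError(
            "supply either 'b' or 'm_markers', not both (ambiguous)")
    if b is None and m_markers is None:
        raise ParameterError("one of 'b' or 'm_markers' is required")
    if b is None:
        m = validate_field("m_markers", m_markers)
        b = m / (m + me)
    else:
        b = validate_field("b", b)
    theta = n * b * h2 / me
    return math.sqrt(b * theta / (1.0 + theta))


def rabier(n_train, h2, me) -> float:
    """Accuracy without the unit-variance assumption:
    ``sqrt((h2/(1-h2)) / (Me/N + h2/(1-h2)))``.

    Requires ``h2 < 1`` strictly; at ``h2 = 1`` the signal-to-noise ratio
    ``h2/(1-h2)`` diverges and the accuracy tends to its limiting value 1.
    """
    n = validate_field("n_train", n_train)
    h2 = validate_field("h2", h2)
    me = validate_field("me", me)
    if h2 >= 1.0:
        raise ParameterError(
            "h2 must be strictly below 1 (as h2 -> 1 the accuracy tends to "
            "its limiting value 1)")
    snr = h2 / (1.0 - h2)
    return math.sqrt(snr / (me / n + snr))


def rabier_eterm(h2, eterm) -> float:
    """Ridge-regression form of :func:`rabier` with ``Me/N`` replaced by the
    expectation term ``E(||x' X' V^-1||^2)``:
    ``sqrt((h2/(1-h2)) / (eterm + h2/(1-h2)))``.

    With ``eterm = Me/N`` this equals :func:`rabier` exactly.  See
    :mod:`gpasim.eterm` for estimating the expectation term from marker
    data.
    """
    h2 = validate_field("h2", h2)
    if h2 >= 1.0:
        raise ParameterError(
            "h2 must be strictly below 1 (as h2 -> 1 the accuracy tends to "
            "its limiting value 1)")
    eterm = validate_field("eterm", eterm)
    snr = h2 / (1.0 - h2)
    return math.sqrt(snr / (eterm + snr))


def deloscampos(b, h2) -> float:
    """Upper limit of achievable accuracy: ``sqrt((1 - (1-b)**2) * h2)``.

    ``b`` is the average regression coefficient of marker-based genomic
    relationships on relationships at causal loci.  Does not depend on
    ``Me``.  Bounded above by ``sqrt(h2)`` (attained at ``b = 1``).
    """
    b = validate_field("b", b)
    h2 = validate_field("h2", h2)
    return math.sqrt((1.0 - (1.0 - b) ** 2) * h2)


def karaman(n_train, h2_m, me) -> float:
    """Phenotype-vs-EBV correlation form:
    ``sqrt(h2_M * N h2_M / (N h2_M + Me))`` with genomic heritability
    ``h2_M`` (variance captured by regression on markers)."""
    n = validate_field("n_train", n_train)
    h2_m = validate_field("h2_m", h2_m)
    me = validate_field("me", me)
    nh2 = n * h2_m
    return math.sqrt(h2_m * nh2 / (nh2 + me))


def wientjes(n_a, n_b, h2_a, h2_b, me_ac, me_bc,
             r_g_ac, r_g_bc, r_g_ab, b_ac, b_bc) -> float:
    """Accuracy in population C predicted from training populations A and B.

    Computed as ``sqrt(a' P^-1 a)`` with

    - ``a = [b_AC r_GAC sqrt(h2_A/Me_AC), b_BC r_GBC sqrt(h2_B/Me_BC)]``
    - ``P = [[h2_A/Me_AC + 1/N_A, c], [c, h2_B/Me_BC + 1/N_B]]`` where
      ``c = r_GAB sqrt(h2_A h2_B / (Me_AC Me_BC))``.

    The published typesetting distributes the square root over the three
    factors of the quadratic form; the scalar quadratic form used here is
    the well-defined reading and reproduces all stated reductions (e.g.
    with population B inert and ``b_AC = r_GAC = 1`` it collapses to
    :func:`daetwyler` on A's parameters).  Invariant under exchanging the
    A and B labels.
    """
    p = MultiPopParams(n_a=n_a, n_b=n_b, h2_a=h2_a, h2_b=h2_b,
                       me_ac=me_ac, me_bc=me_bc, r_g_ac=r_g_ac,
                       r_g_bc=r_g_bc, r_g_ab=r_g_ab, b_ac=b_ac, b_bc=b_bc)
    da = p.h2_a / p.me_ac
    db = p.h2_b / p.me_bc
    off = p.r_g_ab * math.sqrt(da * db)
    P = np.array([[da + 1.0 / p.n_a, off],
                  [off, db + 1.0 / p.n_b]], dtype=float)
    a = np.array([p.b_ac * p.r_g_ac * math.sqrt(da),
                  p.b_bc * p.r_g_bc * math.sqrt(db)], dtype=float)
    # 2x2 reciprocal condition estimate (1-norm) before solving.
    det = P[0, 0] * P[1, 1] - P[0, 1] * P[1, 0]
    norm1 = max(abs(P[0, 0]) + abs(P[1, 0]), abs(P[0, 1]) + abs(P[1, 1]))
    inv_norm1 = (max(abs(P[1, 1]) + abs(P[1, 0]),
                     abs(P[0, 1]) + abs(P[0, 0])) / abs(det)) if det else math.inf
    rcond = 1.0 / (norm1 * inv_norm1) if math.isfinite(inv_norm1) else 0.0
    if rcond < _RCOND_MIN:
        raise LinearAlgebraError(
            f"coefficient matrix is singular or ill-conditioned "
            f"(reciprocal condition estimate {rcond:.3e} < {_RCOND_MIN})")
    q = float(a @ np.linalg.solve(P, a))
    return _sqrt_clamped(q, "wientjes")


# ---------------------------------------------------------------------------
# registry and dispatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormulaInfo:
    """Registry entry for one deterministic formula."""

    formula_id: str
    citation_label: str
    required_params: tuple
    func: Callable[..., float] = field(repr=False)
    assumptions: str = ""
    optional_params: tuple = ()
    multi_population: bool = False


REGISTRY: tuple[FormulaInfo, ...] = (
    FormulaInfo(
        formula_id="daetwyler",
        citation_label="(a) Daetwyler et al. 2008/2010",
        required_params=("n_train", "h2", "me"),
        func=daetwyler,
        assumptions=("markers treated as fixed; independent QTL; complete "
                     "marker-QTL LD; residual variance 1 with genetic + "
                     "residual variance = 1"),
    ),
    FormulaInfo(
        formula_id="goddard2009",
        citation_label="(b) Goddard 2009",
        required_params=("n_train", "h2", "me", "ne"),
        func=goddard2009,
        assumptions=("markers treated as random; complete marker-QTL LD; "
                     "normally distributed QTL effects"),
    ),
    FormulaInfo(
        formula_id="goddard2011",
        citation_label="(c) Goddard et al. 2011",
        required_params=("n_train", "h2", "me", "b"),
        func=goddard2011,
        assumptions=("incomplete marker-QTL LD; finite marker number; "
                     "b = M/(M+Me) when derived from a marker count"),
        optional_params=("m_markers",),
    ),
    FormulaInfo(
        formula_id="rabier",
        citation_label="(d) Rabier et al. 2016",
        required_params=("n_train", "h2", "me"),
        func=rabier,
        assumptions="no unit-variance constraint; h2 strictly below 1",
    ),
    FormulaInfo(
        formula_id="rabier_eterm",
        citation_label="(e) Rabier et al. 2016 (ridge-regression form)",
        required_params=("h2", "eterm"),
        func=rabier_eterm,
        assumptions=("all markers fitted simultaneously via ridge "
                     "regression; eterm = E(||x' X' V^-1||^2) replaces Me/N"),
    ),
    FormulaInfo(
        formula_id="deloscampos",
        citation_label="(f) de los Campos et al. 2013",
        required_params=("b", "h2"),
        func=deloscampos,
        assumptions=("upper limit of achievable accuracy; b is the average "
                     "regression of marker-based on causal-locus "
                     "relationships; no dependence on Me"),
    ),
    FormulaInfo(
        formula_id="karaman",
        citation_label="(g) Karaman et al. 2016",
        required_params=("n_train", "h2_m", "me"),
        func=karaman,
        assumptions=("accuracy as correlation between phenotypes and "
                     "estimated breeding values; genomic heritability h2_M"),
    ),
    FormulaInfo(
        formula_id="wientjes",
        citation_label="(h) Wientjes et al. 2016",
        required_params=("n_a", "n_b", "h2_a", "h2_b", "me_ac", "me_bc",
                         "r_g_ac", "r_g_bc", "r_g_ab", "b_ac", "b_bc"),
        func=wientjes,
        assumptions=("two training populations A and B predicting a third "
                     "population C; b_AC/b_BC are square roots of captured "
                     "variance fractions"),
        multi_population=True,
    ),
)

FORMULA_IDS: tuple[str, ...] = tuple(info.formula_id for info in REGISTRY)
_BY_ID: dict[str, FormulaInfo] = {info.formula_id: info for info in REGISTRY}


def get_info(formula_id: str) -> FormulaInfo:
    """Look up one registry entry by identifier."""
    try:
        return _BY_ID[formula_id]
    except KeyError:
        raise FormulaLookupError(
            f"unknown formula {formula_id!r}; valid identifiers: "
            f"{', '.join(FORMULA_IDS)}")


def list_formulas() -> Sequence[FormulaInfo]:
    """All eight registry entries, in the canonical (a)-(h) order."""
    return REGISTRY


def required_params(formula_id: str) -> tuple:
    return get_info(formula_id).required_params


def evaluate(formula_id: str, params: Mapping[str, object] | WithinPopParams | MultiPopParams) -> float:
    """Dispatch to a formula by identifier.

    ``params`` may be a mapping of field names to values (extraneous keys
    are rejected), a :class:`WithinPopParams`, or a :class:`MultiPopParams`.
    The result is identical to calling the formula function directly.
    """
    info = get_info(formula_id)
    if isinstance(params, (WithinPopParams, MultiPopParams)):
        kwargs = {}
        for name in info.required_params + info.optional_params:
            value = getattr(params, name, None)
            if value is not None:
                kwargs[name] = value
    else:
        allowed = set(info.required_params) | set(info.optional_params)
        extra = set(params) - allowed
        if extra:
            raise ParameterError(
                f"formula {formula_id!r} does not accept parameter(s) "
                f"{sorted(extra)}; accepted: {sorted(allowed)}")
        kwargs = dict(params)
    # b and m_markers are alternatives in goddard2011; the function itself
    # arbitrates between them, so neither is hard-required here.
    hard_required = [n for n in info.required_params
                     if not (info.formula_id == "goddard2011" and n == "b")]
    missing = [n for n in hard_required if n not in kwargs]
    if missing:
        raise ParameterError(
            f"formula {formula_id!r} is missing required parameter(s) "
            f"{missing}")
    return info.func(**kwargs)
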