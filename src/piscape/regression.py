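"""Least-squares model-family search for compartment mean pI.

The question the search answers: which function of the organelle covariates
(local pH, membrane charge) best approximates the mean pI of each
compartment's distribution?  Candidate families are fitted by ordinary least
squares on their basis expansion — power and exponential forms in log space —
ranked by the coefficient of determination evaluated in the original response
space, and each winner is validated by the Spearman correlation between
fitted and observed values.

The bivariate catalogue enumerates every non-empty subset of the monomials
x1^i * x2^j (1 <= i+j <= 3) together with an intercept, 511 families in all,
plus the single-covariate families applied to each variable — a reproducible
superset of the "many functions" style of exhaustive curve-fitting searches.
Selection is by raw R^2 (no train/test split or information criterion); at
n ~ 8 compartments this overfits by construction, which is why the Spearman
validation and n are always reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np

from .environment import CompartmentEnvironment
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
    SingularFitError,
)
from .stats import CorrelationResult, r_squared, spearman

logger = logging.getLogger(__name__)

Mode = Literal["ph", "charge", "both"]

#: exponent pairs (i, j) for the bivariate monomials of total degree 1..3
_BIVARIATE_EXPONENTS = tuple(
    (i, j) for d in (1, 2, 3) for i in range(d, -1, -1) for j in (d - i,)
)


@dataclass(frozen=True)
class ModelFamily:
    """A candidate function family: named basis terms over 1 or 2 covariates.

    ``terms`` are monomial exponent tuples; for ``fit_space="log"`` families
    (power, exponential) the basis applies to the log-transformed response.
    """

    name: str
    arity: int
    terms: tuple[tuple[int, ...], ...]
    fit_space: Literal["original", "log"] = "original"
    kind: Literal["polynomial", "linear", "power", "exponential", "logarithmic"] = (
        "polynomial"
    )
    log_x: bool = False  # basis uses log(x1) instead of x1

    def __post_init__(self) -> None:
        if not self.terms:
            raise ParameterError(f"family {self.name!r} has no terms")
        if len(set(self.terms)) != len(self.terms):
            raise ParameterError(f"family {self.name!r} has duplicate terms")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def _basis_input(self, X: np.ndarray) -> np.ndarray:
        if self.log_x or self.fit_space == "log" and self.kind == "power":
            if np.any(X <= 0.0):
                raise ParameterError(
                    f"family {self.name!r} requires strictly positive covariates"
                )
            return np.log(X)
        return X

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        Xb = self._basis_input(X)
        cols = [np.prod(Xb**np.asarray(t), axis=1) for t in self.terms]
        return np.column_stack(cols)

    def predict(self, coefficients: np.ndarray, X: np.ndarray) -> np.ndarray:
        yhat = self.design_matrix(X) @ coefficients
        if self.fit_space == "log":
            return np.exp(yhat)
        return yhat


@dataclass(frozen=True)
class RegressionFit:
    family: ModelFamily
    coefficients: np.ndarray
    r2: float
    spearman_fit: CorrelationResult | None
    n: int

    def format_equation(self, var_names: Sequence[str] = ("x1", "x2")) -> str:
        def term_name(t: tuple[int, ...]) -> str:
            if not any(t):
                return "1"
            parts = []
            for power, var in zip(t, var_names):
                if power == 0:
                    continue
                base = f"log({var})" if self.family.log_x else var
                parts.append(base if power == 1 else f"{base}^{power}")
            return "*".join(parts)

        body = " + ".join(
            f"{c:.4g}*{term_name(t)}" if any(t) else f"{c:.4g}"
            for c, t in zip(self.coefficients, self.family.terms)
        )
        if self.family.fit_space == "log":
            return f"y = exp({body})"
        return f"y = {body}"


def _poly_terms_1d(degree: int) -> tuple[tuple[int, ...], ...]:
    return tuple((d,) for d in range(degree + 1))


def univariate_catalogue() -> list[ModelFamily]:
    """Linear, polynomial (deg 2-3), power, exponential and logarithmic families."""
    return [
        ModelFamily("linear", 1, _poly_terms_1d(1), kind="linear"),
        ModelFamily("poly2", 1, _poly_terms_1d(2), kind="polynomial"),
        ModelFamily("poly3", 1, _poly_terms_1d(3), kind="polynomial"),
        ModelFamily("logarithmic", 1, _poly_terms_1d(1), kind="logarithmic", log_x=True),
        ModelFamily("power", 1, _poly_terms_1d(1), fit_space="log", kind="power"),
        ModelFamily("exponential", 1, _poly_terms_1d(1), fit_space="log", kind="exponential"),
    ]


def bivariate_catalogue(max_degree: int = 3) -> list[ModelFamily]:
    """All intercept-plus-monomial-subset polynomial families in two covariates.

    With max_degree 3 there are 9 monomials and 511 non-empty subsets; the
    full degree-1 subset doubles as the bivariate linear model.
    """
    monomials = tuple(t for t in _BIVARIATE_EXPONENTS if sum(t) <= max_degree)
    families = []
    for size in range(1, len(monomials) + 1):
        for subset in combinations(monomials, size):
            terms = ((0, 0),) + subset
            name = "poly(" + ",".join(
                "*".join(
                    f"x{k + 1}" + (f"^{p}" if p > 1 else "")
                    for k, p in enumerate(t)
                    if p
                )
                for t in subset
            ) + ")"
            kind = "linear" if set(subset) <= {(1, 0), (0, 1)} else "polynomial"
            families.append(ModelFamily(name, 2, terms, kind=kind))
    return families


def fit_family(
    family: ModelFamily,
    covariates: Sequence[Sequence[float]] | np.ndarray,
    y: Sequence[float],
) -> RegressionFit:
    """Fit one family by (possibly log-space) ordinary least squares.

    R^2 and the Spearman validation are always computed on the original
    response scale, regardless of the space the family was fitted in.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and family.arity == 1:
        X = X.T
    if X.ndim != 2 or X.shape[1] != family.arity:
        raise ParameterError(
            f"family {family.name!r} expects {family.arity} covariate(s), "
            f"got shape {X.shape}"
        )
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if X.shape[0] != n:
        raise ParameterError("covariates and response lengths differ")
    if n < family.n_terms:
        raise InsufficientDataError(
            f"family {family.name!r}: {family.n_terms} terms but only {n} points"
        )
    if family.fit_space == "log":
        if np.any(yv <= 0.0):
            raise ParameterError(
                f"family {family.name!r} requires a strictly positive response"
            )
        target = np.log(yv)
    else:
        target = yv
    design = family.design_matrix(X)
    coeffs, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < family.n_terms:
        raise SingularFitError(f"family {family.name!r}: rank-deficient design")
    fitted = family.predict(coeffs, X)
    r2 = r_squared(yv, fitted)
    try:
        sp = spearman(yv, fitted)
    except DegenerateInputError:
        sp = None
    return RegressionFit(family=family, coefficients=coeffs, r2=r2, spearman_fit=sp, n=n)


def search(
    families: Sequence[ModelFamily],
    covariates: Sequence[Sequence[float]] | np.ndarray,
    y: Sequence[float],
) -> list[RegressionFit]:
    """Fit every applicable family and rank by R^2 (ties: fewer terms, then name)."""
    fits: list[RegressionFit] = []
    for family in families:
        try:
            fits.append(fit_family(family, covariates, y))
        except (ParameterError, SingularFitError, InsufficientDataError) as exc:
            logger.debug("skipping %s: %s", family.name, exc)
    if not fits:
        raise ParameterError("no family in the catalogue is applicable to this data")
    fits.sort(key=lambda f: (-f.r2, f.family.n_terms, f.family.name))
    return fits


def compartment_regression(
    environment: Sequence[CompartmentEnvironment],
    mean_pis: Mapping[str, float],
    mode: Mode = "both",
    exclude: frozenset[str] | set[str] = frozenset({"cytoskeleton"}),
    families: Sequence[ModelFamily] | None = None,
) -> list[RegressionFit]:
    """Regress compartment mean pI on organelle pH and/or membrane charge.

    Joins the environment table and the mean-pI map on compartment label,
    drops excluded compartments (cytoskeletal proteins polymerize and are not
    truly soluble, so they are excluded by default) and any compartment
    missing a required covariate (e.g. the plasma membrane, which has no
    intra-organelle pH), then runs :func:`search` with the catalogue matching
    *mode*.
    """
    if mode not in ("ph", "charge", "both"):
        raise ParameterError(f"unknown mode {mode!r}")
    rows = []
    for env in environment:
        label = env.compartment
        if label in exclude:
            logger.info("compartment %s excluded from regression", label)
            continue
        if label not in mean_pis:
            continue
        needs_ph = mode in ("ph", "both")
        if needs_ph and env.ph_avg is None:
            logger.info("compartment %s dropped: no local pH available", label)
            continue
        x = {
            "ph": (env.ph_avg,),
            "charge": (env.charge_pct,),
            "both": (env.ph_avg, env.charge_pct),
        }[mode]
        rows.append((label, x, mean_pis[label]))
    if len(rows) < 4:
        raise InsufficientDataError(
            f"only {len(rows)} usable compartments after exclusions; need >= 4"
        )
    rows.sort()  # deterministic join order
    X = np.array([x for _, x, _ in rows], dtype=float)
    y = np.array([v for _, _, v in rows], dtype=float)
    if families is None:
        families = univariate_catalogue() if mode != "both" else bivariate_catalogue()
    return search(families, X, y)
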