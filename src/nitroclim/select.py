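"""Constrained exhaustive covariate selection by BIC.

Candidate covariates are grouped into categories (precipitation metrics,
extreme-precipitation metrics, temperature metrics, surplus terms, land-use
terms, ...), each with a cap on how many members may enter one model — e.g.
at most one extreme-precipitation metric.  Every admissible combination is
fitted and ranked by BIC; one model beats another only when its BIC is lower
by more than 2, so near-ties (delta BIC <= 2) are reported alongside the
winner.  At least one nitrogen-surplus term is required in every candidate:
a nitrogen-loading model without a nitrogen source is physically
meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd

from .gam import LoadGAM, TermSpec, fit_loading_model

__all__ = ["Category", "CandidateCatalog", "SelectionResult", "enumerate_sets", "BICSearch", "select"]

logger = logging.getLogger(__name__)

DELTA_BIC_TIE = 2.0


@dataclass(frozen=True)
class Category:
    """A named group of interchangeable candidate covariates."""

    name: str
    members: tuple[str, ...]
    max_allowed: int
    min_allowed: int = 0

    def __post_init__(self):
        if not 0 <= self.min_allowed <= self.max_allowed <= len(self.members):
            raise ValueError(
                f"category {self.name!r}: need 0 <= min <= max <= size"
            )


@dataclass(frozen=True)
class CandidateCatalog:
    categories: tuple[Category, ...]

    def __post_init__(self):
        seen = set()
        for c in self.categories:
            dup = seen & set(c.members)
            if dup:
                raise ValueError(f"covariates in multiple categories: {sorted(dup)}")
            seen |= set(c.members)

    @property
    def n_candidates(self) -> int:
        return sum(len(c.members) for c in self.categories)

    def n_models(self) -> int:
        """Closed-form count: product over categories of sum_k C(size, k)."""
        total = 1
        for c in self.categories:
            total *= sum(
                comb(len(c.members), k)
                for k in range(c.min_allowed, c.max_allowed + 1)
            )
        return total


def enumerate_sets(catalog: CandidateCatalog, max_models: int = 200_000):
    """All covariate sets respecting the per-category caps, in deterministic
    (category, lexicographic) order."""
    n = catalog.n_models()
    if n > max_models:
        raise ValueError(
            f"catalog enumerates {n} candidate models, above the cap of {max_models}"
        )
    per_category = [
        [
            combo
            for k in range(c.min_allowed, c.max_allowed + 1)
            for combo in combinations(c.members, k)
        ]
        for c in catalog.categories
    ]
    for choice in product(*per_category):
        yield tuple(cov for combo in choice for cov in combo)


@dataclass
class SelectionResult:
    """Ranked candidate models with the delta-BIC <= 2 near-tie set."""

    table: pd.DataFrame  # columns: covariates, bic, edf, delta_bic; BIC-sorted
    selected: tuple[str, ...]
    near_ties: list[tuple[str, ...]]
    models: dict  # frozenset(covariates) -> fitted LoadGAM


class BICSearch:
    """Exhaustive constrained BIC model search (estimator-style).

    Parameters
    ----------
    catalog : CandidateCatalog
    term_kinds : dict
        Covariate name -> "smooth" | "linear" (default linear).
    basis_size : int
        Basis size for smooth terms.
    load_col : str
        Response column of the records table.

    After :meth:`fit`: ``result_`` (a :class:`SelectionResult`) and
    ``best_model_`` (the winning fitted :class:`LoadGAM`).
    """

    def __init__(self, catalog, term_kinds=None, basis_size=10, load_col="Q_TN",
                 max_models=200_000):
        self.catalog = catalog
        self.term_kinds = term_kinds or {}
        self.basis_size = basis_size
        self.load_col = load_col
        self.max_models = max_models

    def get_params(self, deep=True):
        return {
            "catalog": self.catalog,
            "term_kinds": self.term_kinds,
            "basis_size": self.basis_size,
            "load_col": self.load_col,
            "max_models": self.max_models,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _terms(self, covset):
        return [
            TermSpec(c, self.term_kinds.get(c, "linear"), self.basis_size)
            for c in covset
        ]

    def fit(self, records: pd.DataFrame) -> "BICSearch":
        rows = []
        fitted = {}
        n_failed = 0
        for covset in enumerate_sets(self.catalog, self.max_models):
            try:
                model = fit_loading_model(records, self._terms(covset), self.load_col)
            except Exception as exc:  # failed candidates are logged, not fatal
                logger.warning("candidate %s failed to fit: %s", covset, exc)
                n_failed += 1
                continue
            fitted[frozenset(covset)] = model
            rows.append(
                {"covariates": covset, "bic": model.bic_, "edf": model.edf_}
            )
        if not rows:
            raise RuntimeError("all candidate fits failed")
        table = (
            pd.DataFrame(rows)
            .sort_values(["bic", "covariates"], kind="mergesort")
            .reset_index(drop=True)
        )
        table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
        selected = tuple(table["covariates"].iloc[0])
        ties = [
            tuple(c)
            for c, d in zip(table["covariates"].iloc[1:], table["delta_bic"].iloc[1:])
            if d <= DELTA_BIC_TIE
        ]
        self.result_ = SelectionResult(table, selected, ties, fitted)
        self.best_model_ = fitted[frozenset(selected)]
        self.n_failed_ = n_failed
        return self


def select(
    records: pd.DataFrame, catalog: CandidateCatalog, term_kinds=None, **kwargs
) -> SelectionResult:
    """Functional wrapper over :class:`BICSearch`."""
    return BICSearch(catalog, term_kinds, **kwargs).fit(records).result_
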