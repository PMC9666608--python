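"""Two-stage wrapper feature selection.

Stage one screens every (band, feature, model) triple with
single-feature cross-validation, yielding a 26 x 7 x 4 accuracy grid
(182 cells per band, 728 in total).  Stage two seeds each
(model, band) with the features whose screening accuracy exceeds a
threshold (strictly > 50% by default) and refines the set by greedy
local search over remove/add/swap moves, accepting only strict
cross-validated accuracy improvements.

The search formalizes, as a deterministic procedure, the manual
add/remove/replace refinement loop practitioners run by hand; with fixed
folds the whole stage is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import CVSpec, EvalResult, cross_validate, make_folds
from .features import FEATURE_NAMES, KEY_COLUMNS, LABEL_COLUMN
from .synthetic import BAND_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningGrid",
    "Pattern",
    "preliminary_screen",
    "seed_pattern",
    "greedy_pattern_search",
]


@dataclass
class ScreeningGrid:
    """Single-feature CV accuracies, long format: band, feature, model."""

    table: pd.DataFrame  # columns: band, feature, model, accuracy

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def cells_per_band(self) -> pd.Series:
        return self.table.groupby("band", sort=False).size()

    def accuracy(self, band: str, feature: str, model: str) -> float:
        t = self.table
        sel = t[(t.band == band) & (t.feature == feature) & (t.model == model)]
        if len(sel) != 1:
            raise KeyError((band, feature, model))
        return float(sel.accuracy.iloc[0])

    def wide(self, band: str) -> pd.DataFrame:
        """Feature x model accuracy matrix for one band (heat-map layout)."""
        t = self.table[self.table.band == band]
        return t.pivot(index="feature", columns="model", values="accuracy").reindex(
            index=list(FEATURE_NAMES)
        )


@dataclass(frozen=True)
class Pattern:
    """An ordered feature subset used by one classifier in one band."""

    model_name: str
    band: str
    features: tuple[str, ...]
    provenance: str = "seeded"  # "seeded" | "searched"

    def __post_init__(self):
        if not self.features:
            raise ValueError("pattern must contain at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("pattern contains duplicate features")
        unknown = [f for f in self.features if f not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature name(s) {unknown}")


def preliminary_screen(
    tables: dict[str, pd.DataFrame],
    models: dict,
    cv_spec: CVSpec = CVSpec(),
    features=FEATURE_NAMES,
    bands=BAND_NAMES,
) -> ScreeningGrid:
    """Cross-validate every model on every single feature in every band.

    Folds are materialized once per band table so all cells of one band
    are compared on identical partitions.  Zero-variance features still
    get a cell (the classifier degenerates to majority voting) and are
    flagged in the ``degenerate`` column.
    """
    rows = []
    for band in bands:
        table = tables[band]
        y = table[LABEL_COLUMN].to_numpy()
        groups = table[KEY_COLUMNS[0]].to_numpy()
        folds = make_folds(y, groups, cv_spec)
        for feature in features:
            degenerate = bool(np.ptp(table[feature].to_numpy(dtype=float)) == 0)
            for model_name, model in models.items():
                res = cross_validate(
                    model,
                    table,
                    (feature,),
                    cv_spec,
                    folds=folds,
                    band=band,
                    model_name=model_name,
                )
                rows.append(
                    {
                        "band": band,
                        "feature": feature,
                        "model": model_name,
                        "accuracy": res.metrics.accuracy,
                        "degenerate": degenerate,
                    }
                )
    return ScreeningGrid(table=pd.DataFrame(rows))


def seed_pattern(
    grid: ScreeningGrid,
    model: str,
    band: str,
    threshold: float = 50.0,
) -> Pattern:
    """Select every feature whose screening accuracy is strictly above
    ``threshold`` for this (model, band).  If none qualifies, fall back
    to the single best-screening feature (logged)."""
    t = grid.table
    sel = t[(t.model == model) & (t.band == band)]
    if sel.empty:
        raise KeyError(f"no screening cells for model={model}, band={band}")
    chosen = sel[sel.accuracy > threshold].feature.tolist()
    if not chosen:
        best = sel.loc[sel.accuracy.idxmax(), "feature"]
        logger.info(
            "seed for %s/%s: no feature above %.1f%%, falling back to best "
            "single feature %s",
            model,
            band,
            threshold,
            best,
        )
        chosen = [best]
    ordered = tuple(f for f in FEATURE_NAMES if f in set(chosen))
    return Pattern(model_name=model, band=band, features=ordered, provenance="seeded")


def _canonical(features) -> tuple[str, ...]:
    fs = set(features)
    return tuple(f for f in FEATURE_NAMES if f in fs)


@dataclass
class SearchTrace:
    """Diagnostics of one greedy search run."""

    accepted_accuracies: list[float] = field(default_factory=list)
    n_evaluated: int = 0
    ties: list[tuple[str, ...]] = field(default_factory=list)


def greedy_pattern_search(
    model,
    table: pd.DataFrame,
    seed: Pattern,
    cv_spec: CVSpec = CVSpec(),
    folds: list | None = None,
    max_iter: int = 50,
    tie_tolerance: float = 0.0,
) -> tuple[Pattern, EvalResult, SearchTrace]:
    """Greedy local search over remove-one / add-one / swap-one moves.

    A move is accepted only if it strictly improves pooled CV accuracy;
    among equally-improving moves the one with fewer features wins, then
    canonical feature order breaks remaining ties, so the search is fully
    deterministic given the folds.  Neighbours of the final pattern whose
    accuracy comes within ``tie_tolerance`` of it are reported as
    equivalent alternatives (the "or"-patterns of wrapper selection).
    """
    y = table[LABEL_COLUMN].to_numpy()
    groups = table[KEY_COLUMNS[0]].to_numpy()
    if folds is None:
        folds = make_folds(y, groups, cv_spec)

    cache: dict[tuple[str, ...], EvalResult] = {}
    trace = SearchTrace()

    def evaluate(features: tuple[str, ...]) -> EvalResult:
        key = _canonical(features)
        if key not in cache:
            cache[key] = cross_validate(
                model,
                table,
                key,
                cv_spec,
                folds=folds,
                band=seed.band,
                model_name=seed.model_name,
            )
            trace.n_evaluated += 1
        return cache[key]

    current = _canonical(seed.features)
    current_res = evaluate(current)
    trace.accepted_accuracies.append(current_res.metrics.accuracy)

    for _ in range(max_iter):
        candidates: list[tuple[str, ...]] = []
        unused = [f for f in FEATURE_NAMES if f not in current]
        if len(current) > 1:
            for f in current:
                candidates.append(_canonical(set(current) - {f}))
        for f in unused:
            candidates.append(_canonical(set(current) | {f}))
        for f_out in current:
            for f_in in unused:
                candidates.append(_canonical(set(current) - {f_out} | {f_in}))

        def rank(feats: tuple[str, ...]) -> tuple:
            return (len(feats), tuple(FEATURE_NAMES.index(f) for f in feats))

        best, best_res = current, current_res
        for cand in candidates:
            res = evaluate(cand)
            acc, best_acc = res.metrics.accuracy, best_res.metrics.accuracy
            if acc > best_acc or (
                acc == best_acc and best != current and rank(cand) < rank(best)
            ):
                best, best_res = cand, res
        if best_res.metrics.accuracy <= current_res.metrics.accuracy:
            break
        current, current_res = best, best_res
        trace.accepted_accuracies.append(current_res.metrics.accuracy)

    final_acc = current_res.metrics.accuracy
    trace.ties = [
        feats
        for feats, res in cache.items()
        if feats != current and res.metrics.accuracy >= final_acc - tie_tolerance
    ]
    pattern = Pattern(
        model_name=seed.model_name,
        band=seed.band,
        features=current,
        provenance="searched",
    )
    return pattern, current_res, trace
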