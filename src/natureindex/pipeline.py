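"""End-to-end orchestration: fit -> simulate -> scale -> weight -> aggregate."""

from __future__ import annotations

from typing import Iterable, Sequence

from .aggregation import IndexResult, Scope, compute_index
from .data import Dataset, DatasetError
from .fitting import draw_replicates, fit_dataset
from .scaling import ScaledSimulations, scale_dataset
from .weighting import thematic_mask, weight_table


def simulate_scaled(dataset: Dataset, n_sim: int = 999, seed: int = 0) -> ScaledSimulations:
    """Fit every documented cell, draw replicates, and scale them.

    This is the uncertainty-propagation front half of the pipeline; the
    result feeds any number of differently scoped aggregations.
    """
    fits = fit_dataset(dataset)
    sims = draw_replicates(fits, n_sim=n_sim, seed=seed,
                           duplication_groups=dataset.duplication_groups())
    return scale_dataset(sims, dataset)


def nature_index(
    dataset: Dataset,
    date: int,
    scope: Scope | None = None,
    n_sim: int = 999,
    seed: int = 0,
    scaled: ScaledSimulations | None = None,
    theme_indicators: Iterable[str] | None = None,
) -> IndexResult:
    """Compute the index for one date and scope.

    Pass a precomputed ``scaled`` to reuse one set of Monte-Carlo draws
    across several scopes or dates (recommended: comparisons between
    scopes are then based on the same replicates).
    """
    scope = scope or Scope(label="all")
    if scaled is None:
        scaled = simulate_scaled(dataset, n_sim=n_sim, seed=seed)
    weights = weight_table(
        dataset, date,
        ecosystems=scope.ecosystems, units=scope.units, indicators=scope.indicators,
    )
    if len(weights) == 0:
        raise DatasetError(
            f"no documented indicators in scope {scope.label or scope} at date {date}"
        )
    if theme_indicators is not None:
        weights = thematic_mask(weights, indicators=theme_indicators)
    return compute_index(scaled, weights, dataset, scope, date)


def trend_series(
    dataset: Dataset,
    scope: Scope | None = None,
    dates: Sequence[int] | None = None,
    n_sim: int = 999,
    seed: int = 0,
    scaled: ScaledSimulations | None = None,
) -> list[tuple[int, IndexResult | None]]:
    """One index result per date over a constant scope, for trend plots.

    Dates with zero documentation yield ``(date, None)`` gap entries rather
    than failing, so the series keeps its length.
    """
    dates = list(dates) if dates is not None else list(dataset.dates)
    if not dates:
        raise DatasetError("no dates to compute a trend over")
    if scaled is None:
        scaled = simulate_scaled(dataset, n_sim=n_sim, seed=seed)
    out: list[tuple[int, IndexResult | None]] = []
    for t in dates:
        try:
            out.append((int(t), nature_index(dataset, t, scope=scope, scaled=scaled)))
        except DatasetError:
            out.append((int(t), None))
    return out
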