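"""Reference-state scaling: map observed values to a dimensionless [0, 1] state.

Every indicator is measured in its own natural units (density, abundance,
species richness, ...). Before averaging, each simulated value x is scaled
against the indicator's reference value r > 0 — its expected value in an
ecologically sustainable system — producing a state in [0, 1] where 1 is
the reference condition and 0 complete degradation. Three scaling models
express different interpretations of the reference:

``minimal``
    The reference is a low, precautionary level (e.g. marine management of
    small pelagic fish): degradation means falling below it.
    s = min(x / r, 1).
``maximal``
    The reference is a maximal level above which detrimental effects occur
    (e.g. a proliferating plankton bloom): degradation means exceeding it.
    s = 1 for x <= r, r / x above.
``optimal``
    Any departure from the reference is degradation (e.g. a large herbivore
    that is both huntable and an over-grazer). s = min(minimal, maximal),
    i.e. x / r below the reference and r / x above it, with the unique
    maximum 1 at x = r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CellKey, Dataset, DatasetError
from .fitting import SimulatedValues

MODELS = ("optimal", "minimal", "maximal")


@dataclass(frozen=True)
class ScaledSimulations:
    """Per-cell vectors of scaled states in [0, 1]."""

    values: dict[CellKey, np.ndarray]
    n_sim: int
    seed: int


def scale_value(x, r, model: str):
    """Scale observed value(s) ``x`` against reference ``r`` under ``model``.

    Accepts scalars or arrays for ``x``; the result is clipped to [0, 1].
    ``x`` must be non-negative and ``r`` strictly positive.
    """
    r = float(r)
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"reference value must be > 0, got {r}")
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("observed values must be finite")
    if (x < 0).any():
        raise ValueError("observed values must be non-negative")
    if model == "minimal":
        s = np.minimum(x / r, 1.0)
    elif model == "maximal":
        s = np.where(x <= r, 1.0, r / np.maximum(x, r))
    elif model == "optimal":
        s = np.where(x <= r, x / r, r / np.maximum(x, r))
    else:
        raise ValueError(f"unknown scaling model {model!r}")
    s = np.clip(s, 0.0, 1.0)
    return float(s) if scalar else s


def scale_dataset(sims: SimulatedValues, dataset: Dataset) -> ScaledSimulations:
    """Scale every simulated cell by its own reference state and model."""
    ref = dataset.references.set_index(["indicator_id", "ecosystem_id", "unit_id"])
    out: dict[CellKey, np.ndarray] = {}
    for key, vec in sims.values.items():
        i, j, k, _t = key
        try:
            row = ref.loc[(i, j, k)]
        except KeyError:
            raise DatasetError(
                f"no reference state for simulated cell (indicator={i}, "
                f"ecosystem={j}, unit={k})"
            ) from None
        out[key] = scale_value(vec, float(row["ref_value"]), str(row["scaling_model"]))
    return ScaledSimulations(values=out, n_sim=sims.n_sim, seed=sims.seed)


def scaled_summary(scaled: ScaledSimulations):
    """Per-cell median and quartiles of the scaled state, for inspection."""
    import pandas as pd

    rows = []
    for key in sorted(scaled.values):
        v = scaled.values[key]
        rows.append({
            "indicator_id": key[0], "ecosystem_id": key[1],
            "unit_id": key[2], "date": key[3],
            "q25": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "q75": float(np.quantile(v, 0.75)),
        })
    return pd.DataFrame(rows)
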