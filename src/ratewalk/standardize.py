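"""Direct age standardization of posterior rate draws.

The directly standardized rate is the weighted average of age-specific
rates, SR_t = sum_i w_i R_it, with weights w_i taken from a fixed standard
population and normalized to sum to one.  Standardizing per posterior draw
propagates the model's uncertainty into the standardized rate.

The 2000 US standard million weights for the six 5-year age bands 50-79
ship with the package (``us_standard_million_50_79``); any weight table
with matching stratum labels is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "StandardPopulation",
    "read_standard_population",
    "us_standard_million_50_79",
    "direct_standardize",
]


@dataclass(frozen=True)
class StandardPopulation:
    """Age-stratum weights for direct standardization.

    Weights may be raw standard-population counts or shares; they are
    normalized to sum to one at use.
    """

    strata: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.strata):
            raise ValueError("one weight per stratum required")
        if len(self.strata) != len(set(self.strata)):
            raise ValueError("duplicate stratum labels")
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be finite and > 0")
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "weights", w / w.sum())

    def aligned_to(self, strata) -> np.ndarray:
        """Weights reordered to the given stratum labels.

        Label sets must match exactly: strata in the data but not the
        standard (or vice versa) are an error, because silently dropping a
        stratum would change what the standardized rate means.
        """
        strata = tuple(strata)
        missing = set(strata) - set(self.strata)
        extra = set(self.strata) - set(strata)
        if missing or extra:
            raise ValueError(
                "stratum labels do not match standard population; "
                f"missing from standard: {sorted(map(str, missing))}; "
                f"absent from data: {sorted(map(str, extra))}"
            )
        order = [self.strata.index(s) for s in strata]
        return self.weights[order]


def read_standard_population(path) -> StandardPopulation:
    """Read a ``stratum,weight`` CSV into a :class:`StandardPopulation`."""
    df = pd.read_csv(path, dtype={"stratum": str})
    if not {"stratum", "weight"} <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns 'stratum' and 'weight', got "
            f"{list(df.columns)}"
        )
    return StandardPopulation(
        strata=tuple(df["stratum"]), weights=df["weight"].to_numpy(float)
    )


def us_standard_million_50_79() -> StandardPopulation:
    """2000 US standard million weights for 5-year age bands 50-79."""
    with resources.as_file(
        resources.files("ratewalk") / "data" / "us_standard_million_50_79.csv"
    ) as path:
        return read_standard_population(path)


def direct_standardize(
    draws,
    std: StandardPopulation,
    group=None,
    per: float = 1.0,
) -> np.ndarray:
    """Directly standardized rate draws for one group.

    Returns an array ``(chain, draw, time)``: per draw and period the
    convex combination sum_i w_i R_it over age strata, with weights
    normalized to one.  Being a convex combination, the result always lies
    between the smallest and largest stratum-specific rate.
    """
    w = std.aligned_to(draws.series.strata)
    stratum_rates = draws.stratum_rate_draws(group=group, per=per)
    return np.einsum("...s,s->...", stratum_rates, w)
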