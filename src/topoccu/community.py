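"""Community-level and descriptive summaries across topographic categories.

Two kinds of output: (i) model-based community occupancy — the posterior of
the across-species mean of psi within a category, summarized draw-wise so
it carries a credible interval; (ii) purely descriptive tallies of
independent capture events and observed species richness per category,
which use *all* recorded species, not only the modelled ones, and are not
model-adjusted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .covariates import SiteCovariates
from .detections import EventTable
from .msom import CLASS_COLUMNS, PosteriorDraws, psi_draws_for_category, summarize_posterior

__all__ = ["community_occupancy", "events_by_category", "category_report"]

log = logging.getLogger(__name__)


def community_occupancy(psi_draws: np.ndarray) -> dict:
    """Posterior of the across-species mean occupancy for one category.

    ``psi_draws`` is (species, chains, kept) on the probability scale; the
    community value for each retained draw is the plain average over
    species, so the summary lies between the least and most widespread
    species and inherits a proper 95% BCI.
    """
    arr = np.asarray(psi_draws, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need (n_species >= 1, chains, kept) psi draws")
    return summarize_posterior(arr.mean(axis=0))


def events_by_category(
    events: EventTable, covariates: SiteCovariates, variable: str
) -> pd.DataFrame:
    """Counts, percentages, and richness of independent events per class.

    Species richness counts every recorded species (a species seen in two
    classes counts once in each).  Events at sites without a class label
    for ``variable`` are excluded with a warning.  Classes containing
    sites but no events appear with zero counts.
    """
    col = CLASS_COLUMNS[variable]
    tab = covariates.table
    site_class = tab.set_index("site_id")[col]
    ev = events.events.copy()
    ev["category"] = ev["site_id"].map(site_class)
    missing = ev["category"].isna()
    if missing.any():
        log.warning(
            "%d event(s) at sites with no %s class were excluded", int(missing.sum()), variable
        )
        ev = ev[~missing]

    classes = sorted(site_class.dropna().unique())
    total = len(ev)
    rows = []
    for cls in classes:
        sub = ev[ev["category"] == cls]
        rows.append(
            {
                "variable": variable,
                "class": cls,
                "n_sites": int((site_class == cls).sum()),
                "n_events": len(sub),
                "proportion_of_events": 100.0 * len(sub) / total if total else 0.0,
                "species_richness": sub["species"].nunique(),
            }
        )
    return pd.DataFrame(rows)


def category_report(
    events: EventTable,
    covariates: SiteCovariates,
    variable: str,
    draws: PosteriorDraws | None = None,
) -> pd.DataFrame:
    """Descriptive table per class, with community psi when a fit is given."""
    report = events_by_category(events, covariates, variable)
    if draws is not None:
        means, lo, hi = [], [], []
        for cls in report["class"]:
            if cls in draws.spec.classes:
                psi = np.stack(
                    [psi_draws_for_category(draws, sp, cls) for sp in draws.spec.species]
                )
                summ = community_occupancy(psi)
                means.append(summ["mean"])
                lo.append(summ["q2.5"])
                hi.append(summ["q97.5"])
            else:  # class absent from the fitted design (e.g. no modelled sites)
                means.append(np.nan)
                lo.append(np.nan)
                hi.append(np.nan)
        report["community_psi"] = means
        report["community_psi_q2.5"] = lo
        report["community_psi_q97.5"] = hi
    return report
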