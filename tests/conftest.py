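import pandas as pd
import pytest

from metaroi.cohort import FeatureKey, RoiSummary, detectability_table
from metaroi.reference import REFERENCE_DETECTABILITY, REFERENCE_GROUP_STATS


@pytest.fixture(scope="session")
def reference_summaries() -> list[RoiSummary]:
    """All published per-feature group statistics as RoiSummary objects."""
    return [
        RoiSummary(feature=FeatureKey(region, measure), stats=stats)
        for (region, measure), stats in REFERENCE_GROUP_STATS.items()
    ]


@pytest.fixture(scope="session")
def reference_det_table(reference_summaries) -> pd.DataFrame:
    """Detectability table computed from the published group statistics."""
    return detectability_table(reference_summaries)


@pytest.fixture(scope="session")
def published_det_table() -> pd.DataFrame:
    """Detectability table carrying the published AUC values themselves.

    The published ventricle AUCs were computed empirically on subject-level
    data and differ from the binormal formula, so ranking checks against
    the published ordering must use the published AUC column as input.
    """
    rows = []
    for (region, measure, pair), (auc, pct) in REFERENCE_DETECTABILITY.items():
        rows.append(
            {
                "region": region,
                "measure": measure,
                "pair": pair,
                "auc": auc,
                "percent_change": float(pct),
            }
        )
    return pd.DataFrame(rows)
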