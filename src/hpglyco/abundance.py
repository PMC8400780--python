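"""Per-site normalization to relative abundances and descriptive surfaces.

Peak areas are compositional within a glycosylation site: each patient's
areas are divided by the patient's total area over all isomer entries of
that site, mirroring the per-site normalization of the acquisition
workflow. The group-level class summary (the pie-chart surface) and the
z-scored heat-map matrix are computed from the normalized table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .glyco_model import GlycanClass, classify_glycan, parse_glycan_code
from .quant import QuantTable

__all__ = [
    "RelAbundanceTable",
    "normalize_by_site",
    "glycome_class_summary",
    "heatmap_matrix",
]


@dataclass
class RelAbundanceTable:
    """Patients × isomer entries relative abundances (sum to 1 per site)."""

    values: pd.DataFrame
    #: patients whose site total area was zero (all entries flagged missing)
    missing_sites: list[tuple[str, str]] = field(default_factory=list)

    @staticmethod
    def site_of(column: str) -> str:
        return column.split("|")[0]

    def site_columns(self, site: str) -> list[str]:
        return [c for c in self.values.columns if self.site_of(c) == site]


def _columns_by_site(columns) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for c in columns:
        out.setdefault(c.split("|")[0], []).append(c)
    return out


def normalize_by_site(qt: QuantTable | pd.DataFrame) -> RelAbundanceTable:
    """Divide each patient's areas by that patient's per-site total.

    Idempotent on already-normalized tables. A patient-site with zero total
    gets NaN entries and is recorded in ``missing_sites`` rather than
    dropped.
    """
    areas = qt.areas if isinstance(qt, QuantTable) else qt
    if (areas.values < 0).any():
        raise ValueError("peak areas must be non-negative")
    rel = areas.astype(float).copy()
    missing: list[tuple[str, str]] = []
    for site, cols in _columns_by_site(areas.columns).items():
        totals = areas[cols].sum(axis=1)
        zero = totals == 0
        rel.loc[~zero, cols] = areas.loc[~zero, cols].div(totals[~zero], axis=0)
        rel.loc[zero, cols] = np.nan
        missing.extend((pid, site) for pid in areas.index[zero])
    return RelAbundanceTable(values=rel, missing_sites=missing)


def glycome_class_summary(
    rt: RelAbundanceTable,
    site: str,
    groups: pd.Series | dict,
) -> pd.DataFrame:
    """Per-group mean class fractions at one site.

    For every patient the relative abundances are summed within each glycan
    class (sialylated / sialylated-fucosylated / other); the summary is the
    mean of these per-patient fractions over each group's patients, so each
    group row sums to 1.
    """
    groups = pd.Series(groups)
    cols = rt.site_columns(site)
    if not cols:
        raise ValueError(f"no columns for site {site}")
    cls_of = {c: classify_glycan(parse_glycan_code(c.split("|")[1])).value for c in cols}
    per_patient = pd.DataFrame(
        {
            cls.value: rt.values[[c for c in cols if cls_of[c] == cls.value]].sum(axis=1)
            for cls in GlycanClass
        }
    )
    rows = {}
    for group in pd.unique(groups):
        members = groups.index[groups == group]
        members = per_patient.index.intersection(members)
        if len(members) == 0:
            raise ValueError(f"group {group!r} has no patients in the table")
        rows[group] = per_patient.loc[members].mean()
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out


def heatmap_matrix(
    rt: RelAbundanceTable,
    site: str,
    groups: pd.Series | dict,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-feature z-score matrix (features × patients) with orderings.

    Each feature (isomer entry) is centered and scaled across patients;
    zero-variance features are flagged by an all-zero row. Columns are
    ordered cirrhosis first then HCC; rows by average-linkage hierarchical
    clustering of the z-score profiles (Euclidean distance).
    """
    groups = pd.Series(groups)
    cols = rt.site_columns(site)
    data = rt.values[cols]
    if len(data) < 2:
        raise ValueError("need at least two patients to z-score features")
    centered = data - data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    z = centered.div(sd.where(sd > 0, np.inf), axis=1)  # zero-variance -> 0 rows
    matrix = z.T  # features x patients
    col_order = sorted(
        matrix.columns, key=lambda pid: (groups.get(pid, "") != "cirrhosis", groups.get(pid, ""), pid)
    )
    if len(matrix) > 2:
        linkage = average(pdist(matrix.values))
        row_order = [matrix.index[i] for i in leaves_list(linkage)]
    else:
        row_order = list(matrix.index)
    return matrix.loc[row_order, col_order], row_order, col_order
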