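"""Surface-topology quality indices and quality thresholding.

A perfectly reconstructed cortical hemisphere is a topological sphere: its
triangle mesh has Euler characteristic chi = V - E + F = 2. Each topological
defect (handle/hole) in the reconstruction lowers chi by 2, so the defect
index (2 - chi)/2 counts handles and serves as a higher-is-worse automated
quality index. The subject-level index sums the two hemispheres.

Quality thresholds are median + k * MAD cutoffs (optionally per site) or
absolute score cutoffs; `apply_quality_filter` turns either into a filtered
cohort plus an auditable exclusion report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, DomainError, EmptyInputError, SchemaError
from .fs_io import CohortTable, TriMesh


# ---------------------------------------------------------------------------
# Metric direction conventions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCMetricSpec:
    """A named quality column and the direction of its scale.

    ``higher_worse`` (the FSQC score, Euler defect index, motion ratings) or
    ``higher_better`` (e.g. a Qoala-T certainty score). Every analysis uses
    the direction to orient signs so that a positive association always means
    "worse quality goes with larger phenotype values".
    """

    name: str
    direction: Literal["higher_worse", "higher_better"] = "higher_worse"
    source: Literal["computed", "supplied"] = "supplied"

    def worseness(self, values: np.ndarray | pd.Series) -> np.ndarray:
        """Values on a higher-is-worse scale (negated if higher_better)."""
        v = np.asarray(values, float)
        return -v if self.direction == "higher_better" else v


FSQC_METRIC = QCMetricSpec("fsqc", "higher_worse", "computed")
EULER_METRIC = QCMetricSpec("euler", "higher_worse", "computed")


# ---------------------------------------------------------------------------
# Mesh topology
# ---------------------------------------------------------------------------


@dataclass
class MeshTopology:
    n_vertices: int
    n_edges: int
    n_faces: int
    euler_characteristic: int
    defect_index: float
    n_components: int


def mesh_topology(mesh: TriMesh) -> MeshTopology:
    """Exact V, E, F counts, chi = V - E + F, defect index and component count.

    Edges are unique unordered vertex pairs over the faces; components are
    the connected components of the resulting edge graph (vertices not used
    by any face are ignored).
    """
    f = mesh.faces
    pairs = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    pairs = np.sort(pairs, axis=1)
    edges = np.unique(pairs, axis=0)
    v_used = np.unique(f)
    n_v = len(v_used)
    n_e = len(edges)
    n_f = len(f)
    chi = n_v - n_e + n_f
    # component count over the edge graph
    remap = {v: i for i, v in enumerate(v_used)}
    ei = np.vectorize(remap.get)(edges)
    adj = coo_matrix(
        (np.ones(len(ei)), (ei[:, 0], ei[:, 1])), shape=(n_v, n_v)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return MeshTopology(
        n_vertices=n_v,
        n_edges=n_e,
        n_faces=n_f,
        euler_characteristic=int(chi),
        defect_index=(2 - chi) / 2,
        n_components=int(n_comp),
    )


def subject_euler_index(lh_defects: float, rh_defects: float) -> float:
    """Combined subject quality index: sum of per-hemisphere defect counts (higher = worse)."""
    if lh_defects < 0 or rh_defects < 0:
        raise DomainError("defect indices must be non-negative")
    return float(lh_defects + rh_defects)


def harmonize_supplied_euler(values: np.ndarray | pd.Series) -> np.ndarray:
    """Map signed FreeSurfer-style Euler numbers onto the positive defect scale.

    FreeSurfer reports chi per hemisphere (2 for a perfect sphere, more
    negative with more defects, often summed over hemispheres). |2 - chi| / 2
    per hemisphere equals the defect count; on pre-summed columns the
    absolute-value map preserves the quality ordering, which is all the
    rank-based and threshold analyses need.
    """
    v = np.asarray(values, float)
    return np.abs(v)


# ---------------------------------------------------------------------------
# MAD and thresholds
# ---------------------------------------------------------------------------


def mad(values, scale_constant: float = 1.0) -> float:
    """Median absolute deviation: median(|x - median(x)|) * scale_constant.

    The default is the raw (unscaled) MAD; pass 1.4826 for the
    normal-consistency scaling.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyInputError("mad of empty input")
    return float(np.median(np.abs(v - np.median(v))) * scale_constant)


def mad_thresholds(
    values,
    k_list: Sequence[float],
    scale_constant: float = 1.0,
    groups: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame | np.ndarray:
    """Thresholds median + k * MAD for each k, pooled or per group.

    With ``groups`` (e.g. site labels) the cutoffs are computed within each
    group and a (group x k) frame is returned; otherwise an ascending array.
    """
    ks = np.asarray(list(k_list), float)
    if ks.size == 0 or (ks <= 0).any():
        raise ConfigError("k_list must be non-empty with k > 0")
    ks = np.sort(ks)
    if groups is None:
        v = np.asarray(values, float)
        med = np.median(v[np.isfinite(v)])
        m = mad(v, scale_constant)
        return med + ks * m
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    rows = {}
    for g, grp in df.groupby("group"):
        v = grp["value"].to_numpy()
        med = np.median(v[np.isfinite(v)])
        rows[g] = med + ks * mad(v, scale_constant)
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"k={k:g}" for k in ks])


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    metric: str
    mode: str
    cutoff: float | None
    n_input: int
    n_retained: int
    n_excluded: int
    by_site: dict
    by_diagnosis: dict

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@dataclass
class FilterResult:
    retained: CohortTable
    excluded: pd.DataFrame
    report: ExclusionReport
    groups: pd.Series | None = None  # median_split membership ('low'/'high')


def apply_quality_filter(
    cohort: CohortTable,
    metric: QCMetricSpec,
    cutoff: float | None = None,
    mode: Literal["absolute", "mad_k", "top_fraction", "median_split"] = "absolute",
    k: float | None = None,
    fraction: float | None = None,
    per_site: bool = False,
    scale_constant: float = 1.0,
    strict: bool = False,
) -> FilterResult:
    """Filter a cohort on a quality metric; returns retained rows + exclusion report.

    Retention keeps rows whose quality is at least as good as the cutoff
    (boundary values retained; ``strict=True`` flips to strict retention).
    Modes: ``absolute`` (explicit cutoff on the metric scale), ``mad_k``
    (cutoff = median + k * MAD of the worseness values, optionally per site),
    ``top_fraction`` (exclude the worst ``fraction`` of rows), and
    ``median_split`` (label low/high-quality halves, ties to the better
    group; the retained table is the better half).
    """
    df = cohort.df
    if metric.name not in df.columns:
        raise SchemaError(f"metric column {metric.name!r} not in cohort")
    worse = pd.Series(metric.worseness(df[metric.name]), index=df.index)
    site = df[cohort.schema.site]

    def _keep_for_cutoffs(cut: pd.Series) -> pd.Series:
        return (worse < cut) if strict else (worse <= cut)

    groups = None
    if mode == "absolute":
        if cutoff is None:
            raise ConfigError("absolute mode requires a cutoff")
        cut_w = metric.worseness(np.array([cutoff]))[0]
        keep = _keep_for_cutoffs(pd.Series(cut_w, index=df.index))
        cutoff_out = float(cutoff)
    elif mode == "mad_k":
        if k is None:
            raise ConfigError("mad_k mode requires k")
        if per_site:
            cut = worse.groupby(site).transform(
                lambda v: np.median(v) + k * mad(v, scale_constant)
            )
        else:
            cut = pd.Series(
                np.median(worse) + k * mad(worse, scale_constant), index=df.index
            )
        keep = _keep_for_cutoffs(cut)
        cutoff_out = float(cut.iloc[0]) if not per_site else None
    elif mode == "top_fraction":
        if fraction is None or not (0 <= fraction < 1):
            raise ConfigError("top_fraction mode requires fraction in [0, 1)")
        if per_site:
            cut = worse.groupby(site).transform(lambda v: np.quantile(v, 1 - fraction))
        else:
            cut = pd.Series(np.quantile(worse, 1 - fraction), index=df.index)
        keep = _keep_for_cutoffs(cut)
        cutoff_out = None
    elif mode == "median_split":
        med = float(np.median(worse))
        keep = worse <= med  # ties to the lower (better) group
        groups = pd.Series(np.where(keep, "low", "high"), index=df.index, name="quality_group")
        cutoff_out = med
    else:
        raise ConfigError(f"unknown filter mode {mode!r}")

    retained = cohort.subset(keep.to_numpy())
    excluded = df.loc[~keep].copy()
    dx_col = cohort.schema.diagnosis
    by_dx = (
        excluded[dx_col].value_counts(dropna=False).to_dict() if dx_col in df.columns else {}
    )
    report = ExclusionReport(
        metric=metric.name,
        mode=mode,
        cutoff=cutoff_out,
        n_input=len(df),
        n_retained=len(retained),
        n_excluded=len(excluded),
        by_site=excluded[cohort.schema.site].value_counts().to_dict(),
        by_diagnosis={str(kk): int(vv) for kk, vv in by_dx.items()},
    )
    return FilterResult(retained=retained, excluded=excluded, report=report, groups=groups)
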