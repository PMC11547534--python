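"""Feature-table container, I/O, filtering, imputation, QC-anchored
LOWESS normalization and PCA for quality assessment.

The central object is :class:`FeatureTable`: an aligned feature x sample
matrix of peak areas together with per-feature (m/z, RT) and per-sample
(role, group, time, replicate, injection order) metadata.  Pooled-QC
samples injected at regular intervals anchor the drift-correction step:
for every feature a LOWESS curve of QC intensity versus injection order is
fitted and divided out, which removes the smooth instrumental sensitivity
drift that accumulates over a long injection sequence.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "FilterConfig",
    "read_feature_table",
    "write_feature_table",
    "filter_features",
    "impute_missing",
    "lowess_normalize",
    "pca_scores",
]

#: sample roles recognised throughout the pipeline
ROLES = ("sample", "QC", "control")

# metadata rows of the delimited dialect, in file order; role/group/time
# are mandatory, the remaining two carry the replicate index and the
# injection sequence position needed for drift correction.
_META_ROWS = ("role", "group", "time_h", "replicate", "injection_order")


@dataclass
class FeatureTable:
    """Aligned features x samples peak-area matrix with metadata.

    Parameters
    ----------
    features : DataFrame indexed by feature ID with columns ``mz`` and
        ``rt`` (minutes); extra columns (e.g. ``has_ms2``, ``sn``) are
        carried along untouched.
    samples : DataFrame indexed by sample ID with columns ``role``
        (sample/QC/control), ``group`` (oral/IM/none), ``time_h``,
        ``replicate`` and ``injection_order``.
    areas : DataFrame (features x samples); NaN marks a missing value.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("duplicate feature IDs")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if not self.areas.index.equals(self.features.index):
            raise ValueError("area matrix rows do not match feature IDs")
        if not self.areas.columns.equals(self.samples.index):
            raise ValueError("area matrix columns do not match sample IDs")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative peak areas")
        io_col = self.samples["injection_order"]
        if io_col.duplicated().any():
            raise ValueError("injection orders are not unique")

    # -- convenience selectors -------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, role: Optional[str] = None, group: Optional[str] = None) -> pd.Index:
        mask = pd.Series(True, index=self.samples.index)
        if role is not None:
            mask &= self.samples["role"] == role
        if group is not None:
            mask &= self.samples["group"] == group
        return self.samples.index[mask]

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.features.loc[ids], self.samples, self.areas.loc[ids])

    def subset_samples(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.features, self.samples.loc[ids], self.areas[ids])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.samples.copy(), self.areas.copy())


# ---------------------------------------------------------------------------
# delimited dialect
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if x != x:  # NaN -> blank (missing)
        return ""
    return repr(float(x))


def write_feature_table(t: FeatureTable, path, header_lines: Iterable[str] = ()) -> None:
    """Write the delimited feature-table dialect.

    Layout: optional ``#``-prefixed provenance lines; row 1 sample IDs
    (after ``feature_id,mz,rt``); labelled metadata rows (role, group,
    time_h, replicate, injection_order); then one row per feature with
    m/z, RT and the per-sample areas (blank cell = missing).
    """
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    sids = list(t.samples.index)
    buf.write(",".join(["feature_id", "mz", "rt"] + sids) + "\n")
    for key in _META_ROWS:
        vals = [str(v) for v in t.samples[key].tolist()]
        buf.write(",".join([key, "", ""] + vals) + "\n")
    for fid, row in t.features.iterrows():
        cells = [str(fid), _fmt(row["mz"]), _fmt(row["rt"])]
        cells += [_fmt(v) for v in t.areas.loc[fid, sids].tolist()]
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_feature_table(path) -> FeatureTable:
    """Read the dialect written by :func:`write_feature_table` (lossless)."""
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty feature table")
    header = lines[0].split(",")
    if header[:3] != ["feature_id", "mz", "rt"]:
        raise ValueError(f"{path}: bad header, expected feature_id,mz,rt,...")
    sids = header[3:]
    if len(set(sids)) != len(sids):
        raise ValueError(f"{path}: duplicate sample IDs")
    meta: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        cells = lines[i].split(",")
        if cells[0] not in _META_ROWS:
            break
        if len(cells) != len(header):
            raise ValueError(f"{path}: metadata row {cells[0]!r} has wrong width")
        meta[cells[0]] = cells[3:]
        i += 1
    missing = [k for k in _META_ROWS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing metadata rows {missing}")
    fids, mzs, rts, rows = [], [], [], []
    for ln in lines[i:]:
        cells = ln.split(",")
        if len(cells) != len(header):
            raise ValueError(f"{path}: feature row {cells[0]!r} has wrong width")
        fids.append(cells[0])
        mzs.append(float(cells[1]))
        rts.append(float(cells[2]))
        rows.append([float(c) if c != "" else np.nan for c in cells[3:]])
    if len(set(fids)) != len(fids):
        raise ValueError(f"{path}: duplicate feature IDs")
    features = pd.DataFrame({"mz": mzs, "rt": rts}, index=pd.Index(fids, name="feature_id"))
    samples = pd.DataFrame(
        {
            "role": meta["role"],
            "group": meta["group"],
            "time_h": [float(v) for v in meta["time_h"]],
            "replicate": [int(v) for v in meta["replicate"]],
            "injection_order": [int(v) for v in meta["injection_order"]],
        },
        index=pd.Index(sids, name="sample_id"),
    )
    areas = pd.DataFrame(rows, index=features.index, columns=samples.index, dtype=float)
    return FeatureTable(features, samples, areas)


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the manual-refinement step of feature curation.

    ``min_fill`` is the minimum fraction of samples in which the feature
    must be present (MS-DIAL's Fill%); ``min_sn`` applies only when the
    table carries a per-feature ``sn`` column; ``require_ms2`` applies only
    when a boolean ``has_ms2`` column is present.
    """

    min_fill: float = 0.0
    min_sn: Optional[float] = None
    require_ms2: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fill <= 1.0:
            raise ValueError("min_fill must lie in [0, 1]")


def filter_features(t: FeatureTable, cfg: FilterConfig) -> FeatureTable:
    """Drop features failing the enabled thresholds; feature order kept."""
    keep = pd.Series(True, index=t.features.index)
    fill = t.areas.notna().mean(axis=1)
    keep &= fill >= cfg.min_fill
    if cfg.min_sn is not None and "sn" in t.features.columns:
        keep &= t.features["sn"] >= cfg.min_sn
    if cfg.require_ms2 and "has_ms2" in t.features.columns:
        keep &= t.features["has_ms2"].astype(bool)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_features: dropped %d of %d features", dropped, len(keep))
    return t.subset_features(t.features.index[keep])


def impute_missing(t: FeatureTable, fraction_of_min: float = 0.2) -> FeatureTable:
    """Replace missing cells with ``fraction_of_min`` x the feature's
    minimum observed positive area (default 20%, the MetaboAnalyst rule)."""
    areas = t.areas.copy()
    vals = areas.to_numpy(dtype=float)
    for i, fid in enumerate(areas.index):
        row = vals[i]
        obs = row[~np.isnan(row)]
        obs = obs[obs > 0]
        if obs.size == 0:
            raise ValueError(f"feature {fid!r} has no observed positive value")
        row[np.isnan(row)] = fraction_of_min * obs.min()
    return FeatureTable(t.features, t.samples, pd.DataFrame(vals, index=areas.index, columns=areas.columns))


# ---------------------------------------------------------------------------
# QC-anchored LOWESS normalization
# ---------------------------------------------------------------------------

def lowess_normalize(
    t: FeatureTable,
    span: float = 0.5,
    iters: int = 2,
    min_qc: int = 4,
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Remove injection-order drift using the pooled-QC samples.

    Per feature, a LOWESS curve of QC area versus injection order
    (``frac=span``, ``it=iters`` robustifying passes) is interpolated to
    every injection position; each value is divided by the curve and
    rescaled by the feature's raw QC median, so a drift-free feature is
    returned unchanged.  Features whose QC signal is unusable (fewer than
    ``min_qc`` positive QC values, or a non-positive fitted curve) pass
    through unchanged and are flagged in the report.

    Returns the normalized table and a per-feature report with QC CV
    before/after and a ``normalized`` flag.
    """
    qc_ids = t.sample_ids(role="QC")
    if len(qc_ids) < min_qc:
        raise ValueError(
            f"need at least {min_qc} QC samples for LOWESS normalization, "
            f"found {len(qc_ids)}; rerun in pass-through mode or add QCs"
        )
    qc_io = t.samples.loc[qc_ids, "injection_order"].to_numpy(dtype=float)
    all_io = t.samples["injection_order"].to_numpy(dtype=float)
    order = np.argsort(qc_io)
    qc_io_sorted = qc_io[order]

    out = t.areas.to_numpy(dtype=float).copy()
    report_rows = []
    for i, fid in enumerate(t.areas.index):
        qc_vals = t.areas.loc[fid, qc_ids].to_numpy(dtype=float)[order]
        finite = np.isfinite(qc_vals) & (qc_vals > 0)
        pre_cv = _cv(qc_vals[np.isfinite(qc_vals)])
        ok = finite.sum() >= min_qc
        if ok:
            fitted = _sm_lowess(
                qc_vals[finite], qc_io_sorted[finite],
                frac=span, it=iters, return_sorted=False,
            )
            curve = np.interp(all_io, qc_io_sorted[finite], fitted)
            if np.any(curve <= 0) or not np.all(np.isfinite(curve)):
                ok = False
        if ok:
            qc_median = float(np.median(qc_vals[finite]))
            out[i] = out[i] / curve * qc_median
            post_cv = _cv(out[i][t.samples.index.get_indexer(qc_ids)])
        else:
            logger.info("lowess_normalize: feature %s passed through (insufficient QC signal)", fid)
            post_cv = pre_cv
        report_rows.append((fid, pre_cv, post_cv, bool(ok)))

    norm = FeatureTable(
        t.features, t.samples,
        pd.DataFrame(out, index=t.areas.index, columns=t.areas.columns),
    )
    report = pd.DataFrame(
        report_rows, columns=["feature_id", "qc_cv_before", "qc_cv_after", "normalized"]
    ).set_index("feature_id")
    return norm, report


def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or x.mean() == 0:
        return float("nan")
    return float(x.std(ddof=1) / x.mean())


# ---------------------------------------------------------------------------
# PCA for QC assessment
# ---------------------------------------------------------------------------

def pca_scores(t: FeatureTable, k: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a PCA on log10(area + 1), feature-centered.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the orientation deterministic.  Missing
    values must be imputed first.  Returns (scores, explained-variance
    fractions).
    """
    if t.n_samples < 2 or t.n_features < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    X = t.areas.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before PCA")
    X = np.log10(X + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("degenerate (constant) matrix; PCA undefined")
    from sklearn.decomposition import PCA

    k = min(k, min(X.shape) - 0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for j in range(k):
        lead = loadings[j, np.argmax(np.abs(loadings[j]))]
        if lead < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    scores_df = pd.DataFrame(
        scores, index=t.samples.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return scores_df, pca.explained_variance_ratio_.copy()
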