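"""LC-MS/MS feature-table screening used to select imaging targets.

Oxylipin panels (eicosanoids and octadecanoids) are quantified upstream into
compound × sample concentration tables (pg/mg tissue) with blank and pooled
QC samples alongside the study samples. This module applies the screening
rules — per-measurement S/N > 5, presence in samples above 5-fold blank
levels, QC %RSD < 15 — merges the panels, imputes and Pareto-scales for PCA,
computes airways:parenchyma fold changes with Mann–Whitney/BH statistics,
aggregates stereoisomer pairs, and ranks compounds into an MRM panel subject
to the per-acquisition transition budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pixel_stats import bh_fdr, mann_whitney_u

__all__ = [
    "FeatureTable",
    "ScreenResult",
    "PCAResult",
    "screen_features",
    "merge_panels",
    "impute_and_scale",
    "run_pca",
    "fold_change_stats",
    "select_targets",
    "aggregate_isomers",
    "run_screen",
]

SAMPLE_CLASSES = ("sample", "blank", "QC")

#: Per-acquisition MRM transition budget for the imaging panel.
MAX_PANEL_TRANSITIONS = 6


@dataclass
class FeatureTable:
    """Compound × sample concentration matrix with class metadata.

    ``concentrations`` holds pg/mg tissue (NaN = missing/censored);
    ``sample_meta`` must have a ``class`` column (sample/blank/QC) and a
    ``tissue`` column (airways/parenchyma, NaN for blanks and QCs);
    ``compound_meta`` typically carries pathway, panel and MRM transition.
    ``snr`` is an optional matching matrix of per-measurement S/N.
    """

    concentrations: pd.DataFrame
    sample_meta: pd.DataFrame
    compound_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    snr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if "class" not in self.sample_meta.columns:
            raise ValueError("sample_meta requires a 'class' column")
        unknown = set(self.sample_meta["class"]) - set(SAMPLE_CLASSES)
        if unknown:
            raise ValueError(f"unknown sample classes: {sorted(unknown)}")
        missing = set(self.concentrations.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        vals = self.concentrations.to_numpy(float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.snr is not None and self.snr.shape != self.concentrations.shape:
            raise ValueError("snr matrix must match concentrations shape")

    @property
    def compounds(self) -> list:
        return list(self.concentrations.index)

    def samples_of_class(self, cls: str) -> list:
        meta = self.sample_meta.loc[list(self.concentrations.columns)]
        return list(meta.index[meta["class"] == cls])

    def subset_compounds(self, names: Sequence) -> "FeatureTable":
        return FeatureTable(
            concentrations=self.concentrations.loc[list(names)],
            sample_meta=self.sample_meta,
            compound_meta=(
                self.compound_meta.loc[list(names)]
                if not self.compound_meta.empty
                else self.compound_meta
            ),
            snr=self.snr.loc[list(names)] if self.snr is not None else None,
        )

    def to_csv(self, path, meta_path=None) -> str:
        self.concentrations.to_csv(path)
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path)
        return str(path)

    @classmethod
    def from_csv(cls, path, meta_path, compound_meta_path=None) -> "FeatureTable":
        conc = pd.read_csv(path, index_col=0)
        meta = pd.read_csv(meta_path, index_col=0)
        cmeta = (
            pd.read_csv(compound_meta_path, index_col=0)
            if compound_meta_path
            else pd.DataFrame(index=conc.index)
        )
        return cls(concentrations=conc, sample_meta=meta, compound_meta=cmeta)


# ---------------------------------------------------------------------------
# Screening rules
# ---------------------------------------------------------------------------


def screen_features(
    table: FeatureTable,
    sn_min: float = 5.0,
    blank_ratio: float = 5.0,
    qc_rsd_max: float = 15.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Apply the three screening rules and return the retained table + log.

    (i) measurements with S/N ≤ ``sn_min`` are set to missing (cell-level;
    skipped with a warning when no S/N matrix is attached); (ii) a compound
    is kept only when its mean over study samples exceeds ``blank_ratio`` ×
    its mean over blanks (strict >; skipped when no blanks); (iii) its QC
    %RSD (100·sd/mean over observed QC values) must be below ``qc_rsd_max``
    (strict <; skipped when no QCs). Means use observed values only.
    """
    study = table.samples_of_class("sample")
    if not study:
        raise ValueError("feature table contains no study samples")
    blanks = table.samples_of_class("blank")
    qcs = table.samples_of_class("QC")

    conc = table.concentrations.copy()
    if table.snr is not None:
        conc = conc.where(table.snr > sn_min)
    else:
        warnings.warn("no S/N matrix attached; skipping the S/N > 5 rule")
    if not blanks:
        warnings.warn("no blank samples; skipping the blank-ratio rule")
    if not qcs:
        warnings.warn("no QC samples; skipping the QC %RSD rule")

    records = []
    retained = []
    for comp in conc.index:
        sample_mean = conc.loc[comp, study].mean(skipna=True)
        rec = {"compound": comp, "sample_mean": sample_mean}
        ok = True
        if blanks:
            blank_vals = conc.loc[comp, blanks]
            blank_mean = blank_vals.mean(skipna=True)
            blank_mean = 0.0 if np.isnan(blank_mean) else float(blank_mean)
            passed = bool(
                np.isfinite(sample_mean) and sample_mean > blank_ratio * blank_mean
            )
            rec.update(blank_mean=blank_mean, blank_pass=passed)
            ok &= passed
        if qcs:
            qv = conc.loc[comp, qcs].dropna()
            if len(qv) >= 2 and qv.mean() > 0:
                rsd = 100.0 * qv.std(ddof=1) / qv.mean()
            elif len(qv) >= 1:
                rsd = 0.0
            else:
                rsd = np.nan
            passed = bool(np.isfinite(rsd) and rsd < qc_rsd_max)
            rec.update(qc_rsd=rsd, qc_pass=passed)
            ok &= passed
        rec["retained"] = ok
        records.append(rec)
        if ok:
            retained.append(comp)
    log = pd.DataFrame.from_records(records).set_index("compound")
    out = FeatureTable(
        concentrations=conc.loc[retained],
        sample_meta=table.sample_meta,
        compound_meta=(
            table.compound_meta.loc[retained]
            if not table.compound_meta.empty
            else table.compound_meta
        ),
        snr=table.snr.loc[retained] if table.snr is not None else None,
    )
    return out, log


def merge_panels(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Row-concatenate acquisitions (e.g. eicosanoid + octadecanoid panels).

    Sample ids must align across panels; duplicate compound names are an
    error. A ``panel_source`` provenance column is added to the compound
    metadata.
    """
    if not tables:
        raise ValueError("no tables to merge")
    ref_cols = list(tables[0].concentrations.columns)
    for t in tables[1:]:
        if set(t.concentrations.columns) != set(ref_cols):
            unmatched = set(t.concentrations.columns) ^ set(ref_cols)
            raise ValueError(f"sample ids do not align: {sorted(unmatched)}")
    all_names = [c for t in tables for c in t.compounds]
    dupes = {c for c in all_names if all_names.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate compound names across panels: {sorted(dupes)}")
    conc = pd.concat([t.concentrations[ref_cols] for t in tables])
    metas = []
    for i, t in enumerate(tables):
        m = (
            t.compound_meta.copy()
            if not t.compound_meta.empty
            else pd.DataFrame(index=t.concentrations.index)
        )
        m["panel_source"] = m.get("panel", pd.Series(f"panel{i}", index=m.index))
        metas.append(m)
    snr = None
    if all(t.snr is not None for t in tables):
        snr = pd.concat([t.snr[ref_cols] for t in tables])
    return FeatureTable(
        concentrations=conc,
        sample_meta=tables[0].sample_meta,
        compound_meta=pd.concat(metas),
        snr=snr,
    )


# ---------------------------------------------------------------------------
# Imputation, scaling, PCA
# ---------------------------------------------------------------------------


def impute_and_scale(table: FeatureTable) -> pd.DataFrame:
    """Impute missing values and Pareto-scale for multivariate analysis.

    Missing cells become 20% of the minimum observed value of that compound
    across the entire sample set; each compound is then mean-centered and
    divided by the square root of its standard deviation (Pareto scaling).
    Returns a samples × compounds matrix. A fully missing compound raises.
    """
    conc = table.concentrations
    filled = conc.copy()
    for comp in conc.index:
        row = conc.loc[comp]
        if row.notna().sum() == 0:
            raise ValueError(f"compound {comp!r} has no observed values")
        filled.loc[comp] = row.fillna(0.2 * row.min(skipna=True))
    mat = filled.T  # samples × compounds
    centered = mat - mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    scale = np.sqrt(sd)
    scale[scale == 0] = 1.0  # constant compounds carry no information
    return centered / scale


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def run_pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Principal components of a column-centered (scaled) matrix via SVD.

    Scores are ``U·S`` rows (samples), loadings the right singular vectors
    (compounds). The sign of each component is fixed so its largest-magnitude
    loading is positive. If the matrix rank is below ``n_components`` the
    count is reduced with a warning.
    """
    X = matrix.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("matrix must be complete (impute first)")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"rank {rank} below requested {n_components} components; reduced"
        )
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k].T,
        index=matrix.columns,
        columns=scores.columns,
    )
    total = float((s**2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=evr)


# ---------------------------------------------------------------------------
# Univariate statistics & target selection
# ---------------------------------------------------------------------------


def fold_change_stats(
    table: FeatureTable,
    group_a: str = "airways",
    group_b: str = "parenchyma",
) -> pd.DataFrame:
    """Per-compound fold change (a:b) with Mann–Whitney p and BH q.

    Fold changes and tests use observed (unimputed) concentrations. A
    compound lacking observations in either group is reported untested
    (p, q = NaN); a zero mean in group b yields FC = +inf with a flag.
    """
    meta = table.sample_meta.loc[list(table.concentrations.columns)]
    a_ids = list(meta.index[(meta["class"] == "sample") & (meta["tissue"] == group_a)])
    b_ids = list(meta.index[(meta["class"] == "sample") & (meta["tissue"] == group_b)])
    rows = []
    for comp in table.concentrations.index:
        va = table.concentrations.loc[comp, a_ids].dropna().to_numpy(float)
        vb = table.concentrations.loc[comp, b_ids].dropna().to_numpy(float)
        rec = {
            "compound": comp,
            "n_a": va.size,
            "n_b": vb.size,
            "mean_a": va.mean() if va.size else np.nan,
            "mean_b": vb.mean() if vb.size else np.nan,
        }
        if va.size and vb.size:
            if rec["mean_b"] == 0:
                rec["fc"] = np.inf
                rec["fc_flag"] = "zero-denominator"
            else:
                rec["fc"] = rec["mean_a"] / rec["mean_b"]
                rec["fc_flag"] = ""
            res = mann_whitney_u(va, vb)
            rec["U"] = res.u
            rec["p"] = res.p
            rec["tested"] = True
        else:
            rec.update(fc=np.nan, fc_flag="untested", U=np.nan, p=np.nan, tested=False)
        rows.append(rec)
    out = pd.DataFrame.from_records(rows).set_index("compound")
    out["q"] = np.nan
    tested = out.index[out["tested"]]
    if len(tested):
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


@dataclass
class ScreenResult:
    """Bundle of screening outputs feeding target selection."""

    table: FeatureTable
    filter_log: pd.DataFrame
    stats: pd.DataFrame
    pca: PCAResult | None = None

    @property
    def retained_compounds(self) -> list:
        return list(self.table.concentrations.index)


def select_targets(
    result: ScreenResult | pd.DataFrame,
    max_targets: int,
    min_concentration: float = 0.0,
    max_transitions: int = MAX_PANEL_TRANSITIONS,
) -> pd.DataFrame:
    """Rank screened compounds into an imaging panel.

    The default composite ranks by descending maximum group mean
    concentration, breaking ties by descending ``|log2 FC|`` — making the
    usual informal criteria (concentration and fold change) explicit; the
    rule is a convention and callers may re-rank the returned frame. Compounds below
    ``min_concentration`` are excluded and the panel never exceeds the
    per-acquisition transition budget.
    """
    stats_df = result.stats if isinstance(result, ScreenResult) else result
    df = stats_df.copy()
    df["max_group_mean"] = df[["mean_a", "mean_b"]].max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["abs_log2_fc"] = np.abs(np.log2(df["fc"].to_numpy(float)))
    df = df[df["max_group_mean"] >= min_concentration]
    df = df.sort_values(
        ["max_group_mean", "abs_log2_fc"], ascending=[False, False]
    )
    limit = min(max_targets, max_transitions)
    return df.head(max(limit, 0))


def aggregate_isomers(
    table: FeatureTable, groups: Mapping[str, Sequence[str]]
) -> FeatureTable:
    """Sum grouped stereoisomer rows into single compounds.

    Missing members are treated as 0 in the sum; cells where that happened
    are flagged in the returned table's compound metadata
    (``summed_with_missing`` count), because censored values are not true
    zeros. Unknown members raise.
    """
    conc = table.concentrations
    for name, members in groups.items():
        unknown = [m for m in members if m not in conc.index]
        if unknown:
            raise ValueError(f"unknown compounds in group {name!r}: {unknown}")
    grouped_members = {m for mm in groups.values() for m in mm}
    keep = [c for c in conc.index if c not in grouped_members]
    blocks = [conc.loc[keep]]
    meta_rows = []
    for name, members in groups.items():
        sub = conc.loc[list(members)]
        summed = sub.fillna(0.0).sum(axis=0)
        summed.name = name
        blocks.append(summed.to_frame().T)
        meta_rows.append(
            {
                "compound": name,
                "members": ";".join(members),
                "summed_with_missing": int(sub.isna().to_numpy().sum()),
            }
        )
    new_conc = pd.concat(blocks)
    cmeta = (
        table.compound_meta.loc[keep].copy()
        if not table.compound_meta.empty
        else pd.DataFrame(index=keep)
    )
    gmeta = pd.DataFrame.from_records(meta_rows).set_index("compound")
    cmeta = pd.concat([cmeta, gmeta])
    return FeatureTable(
        concentrations=new_conc,
        sample_meta=table.sample_meta,
        compound_meta=cmeta,
        snr=None,
    )


def run_screen(
    tables: Sequence[FeatureTable],
    sn_min: float = 5.0,
    blank_ratio: float = 5.0,
    qc_rsd_max: float = 15.0,
    n_components: int = 2,
) -> ScreenResult:
    """Full screening pipeline: merge → filter → stats → PCA.

    PCA runs on the imputed, Pareto-scaled study samples of the retained
    table.
    """
    merged = merge_panels(list(tables))
    retained, log = screen_features(
        merged, sn_min=sn_min, blank_ratio=blank_ratio, qc_rsd_max=qc_rsd_max
    )
    stats_df = fold_change_stats(retained)
    pca = None
    if retained.compounds:
        study = retained.samples_of_class("sample")
        sub = FeatureTable(
            concentrations=retained.concentrations[study],
            sample_meta=retained.sample_meta,
            compound_meta=retained.compound_meta,
        )
        scaled = impute_and_scale(sub)
        pca = run_pca(scaled, n_components=n_components)
    return ScreenResult(table=retained, filter_log=log, stats=stats_df, pca=pca)
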