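"""LC-MS feature-table preprocessing.

Three stages, applied by default in this order:

1. PQN — probabilistic quotient normalization against a reference
   vector built from the mean of the pooled-QC injections, correcting
   per-sample dilution.
2. QC-RLSC — per-feature, per-batch robust LOESS of QC intensity
   against injection order, dividing out instrument drift.
3. CV filter — removal of features whose coefficient of variation
   across QC injections exceeds a cutoff (30% by default).

Intensities are a features x injections matrix; injection metadata
carries sample id, injection order, batch label and a QC flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    DegenerateSampleError,
    InvalidParameterError,
    InvariantError,
    MissingQcError,
)

log = logging.getLogger(__name__)

INJECTION_COLUMNS = ["injection_id", "sample_id", "order", "batch", "is_qc"]


@dataclass
class FeatureTable:
    """Feature x injection intensity matrix plus injection metadata.

    ``intensities``: DataFrame, rows = feature ids, columns = injection
    ids; NaN marks a missing measurement.  ``injections``: DataFrame
    indexed by injection id with columns ``sample_id``, ``order``
    (int), ``batch``, ``is_qc`` (bool).  ``feature_metabolites`` maps
    feature id -> metabolite id for annotated features.
    """

    intensities: pd.DataFrame
    injections: pd.DataFrame
    feature_metabolites: dict[str, str] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = set(self.intensities.columns) - set(self.injections.index)
        if missing:
            raise InvariantError(
                f"injections metadata missing for columns: {sorted(missing)[:5]}"
            )
        for col in ("sample_id", "order", "batch", "is_qc"):
            if col not in self.injections.columns:
                raise InvariantError(f"injections table lacks column {col!r}")
        meta = self.injections.loc[list(self.intensities.columns)]
        for batch, grp in meta.groupby("batch"):
            if grp["order"].duplicated().any():
                raise InvariantError(f"duplicate injection order within batch {batch!r}")

    @property
    def qc_columns(self) -> list[str]:
        meta = self.injections.loc[list(self.intensities.columns)]
        return list(meta.index[meta["is_qc"].astype(bool)])

    @property
    def sample_columns(self) -> list[str]:
        meta = self.injections.loc[list(self.intensities.columns)]
        return list(meta.index[~meta["is_qc"].astype(bool)])

    def copy_with(self, intensities: pd.DataFrame, stage: str) -> "FeatureTable":
        return replace(
            self,
            intensities=intensities,
            provenance=self.provenance + [stage],
        )


def read_feature_table(features_path, injections_path) -> FeatureTable:
    intens = pd.read_csv(features_path, sep="\t", index_col=0)
    inj = pd.read_csv(injections_path, sep="\t")
    inj = inj.set_index("injection_id")
    inj["is_qc"] = inj["is_qc"].astype(bool)
    inj["order"] = inj["order"].astype(int)
    return FeatureTable(intensities=intens, injections=inj)


def write_feature_table(table: FeatureTable, features_path, injections_path=None) -> None:
    out = table.intensities.copy()
    out.index.name = "feature_id"
    out.to_csv(features_path, sep="\t")
    if injections_path is not None:
        inj = table.injections.reset_index()
        inj = inj.rename(columns={inj.columns[0]: "injection_id"})
        inj[INJECTION_COLUMNS].to_csv(injections_path, sep="\t", index=False)


def pqn_normalize(table: FeatureTable) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization against the QC-mean reference.

    Reference r_f = mean of feature f over QC injections.  For every
    injection the quotients x_f / r_f are taken over features with
    r_f > 0 and x_f present; the injection is divided by the median
    quotient.  QC injections are normalized by the same rule.

    Returns the normalized table and the per-injection coefficient
    vector (the median quotients).
    """
    qc_cols = table.qc_columns
    if not qc_cols:
        raise MissingQcError("PQN requires at least one QC injection")
    X = table.intensities
    reference = X[qc_cols].mean(axis=1, skipna=True)
    usable = reference > 0
    if not usable.any():
        raise MissingQcError("PQN reference vector has no positive entries")

    coeffs = {}
    for col in X.columns:
        q = X.loc[usable, col] / reference[usable]
        c = float(np.nanmedian(q.to_numpy(dtype=float)))
        if not np.isfinite(c) or c == 0:
            raise DegenerateSampleError(
                f"injection {col!r}: PQN coefficient is zero or undefined"
            )
        coeffs[col] = c
    coeffs = pd.Series(coeffs, name="pqn_coefficient")
    normalized = X.div(coeffs, axis=1)
    return table.copy_with(normalized, "pqn"), coeffs


def _loess_curve(qc_order: np.ndarray, qc_values: np.ndarray, eval_order: np.ndarray,
                 span: float) -> np.ndarray:
    """Robust LOESS fit on QC points, evaluated at eval_order.

    Constant extrapolation beyond the first/last QC injection.
    """
    fit = lowess(
        qc_values,
        qc_order,
        frac=span,
        it=2,
        return_sorted=True,
    )
    return np.interp(eval_order, fit[:, 0], fit[:, 1])


def qc_rlsc(table: FeatureTable, span: float = 0.75) -> FeatureTable:
    """QC-based robust LOESS signal correction, per feature and batch.

    The drift curve is fitted to QC intensities against injection
    order and divided out; each value is rescaled by the median QC
    intensity of its feature in its batch so the corrected scale stays
    interpretable.  Features with < 3 usable QC points in a batch, or
    with a nonpositive fitted curve, are passed through unchanged.
    """
    if not (0 < span <= 1):
        raise InvalidParameterError(f"LOESS span must be in (0, 1], got {span}")
    meta = table.injections.loc[list(table.intensities.columns)]
    X = table.intensities.copy().astype(float)

    for batch, grp in meta.groupby("batch"):
        qc_cols = list(grp.index[grp["is_qc"].astype(bool)])
        all_cols = list(grp.index)
        if len(qc_cols) < 3:
            raise MissingQcError(
                f"batch {batch!r}: QC-RLSC requires >= 3 QC injections, found {len(qc_cols)}"
            )
        qc_order = grp.loc[qc_cols, "order"].to_numpy(dtype=float)
        eval_order = grp.loc[all_cols, "order"].to_numpy(dtype=float)
        srt = np.argsort(qc_order)
        for feat in X.index:
            y = X.loc[feat, qc_cols].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 3:
                log.warning("feature %s batch %s: <3 QC values, passed through", feat, batch)
                continue
            curve = _loess_curve(qc_order[srt][ok[srt]], y[srt][ok[srt]], eval_order, span)
            if np.any(curve <= 0):
                log.warning("feature %s batch %s: nonpositive drift curve, passed through",
                            feat, batch)
                continue
            target = float(np.nanmedian(y[ok]))
            X.loc[feat, all_cols] = X.loc[feat, all_cols].to_numpy(dtype=float) * target / curve
    return table.copy_with(X, "qc_rlsc")


def cv_filter(table: FeatureTable, cutoff_percent: float = 30.0
              ) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove features whose QC coefficient of variation exceeds the cutoff.

    CV = 100 * sd / mean over QC injections (sample sd, n-1).  Features
    with nonpositive QC mean are removed with reason ``nonpositive-mean``.
    Returns the kept table and a DataFrame of removed features with
    columns ``feature_id``, ``cv_percent``, ``reason``.
    """
    qc_cols = table.qc_columns
    if len(qc_cols) < 2:
        raise MissingQcError("CV filter requires >= 2 QC injections")
    qc = table.intensities[qc_cols].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = qc.mean(axis=1, skipna=True)
        sd = qc.std(axis=1, ddof=1, skipna=True)
    cv = 100.0 * sd / mean

    removed = []
    for feat in table.intensities.index:
        if not (mean[feat] > 0):
            removed.append((feat, float(cv[feat]), "nonpositive-mean"))
        elif cv[feat] > cutoff_percent:
            removed.append((feat, float(cv[feat]), "cv-above-cutoff"))
    removed_df = pd.DataFrame(removed, columns=["feature_id", "cv_percent", "reason"])
    kept = table.intensities.drop(index=removed_df["feature_id"].tolist())
    return table.copy_with(kept, f"cv_filter<= {cutoff_percent}"), removed_df


def preprocess(
    table: FeatureTable,
    cv_cutoff: float = 30.0,
    loess_span: float = 0.75,
    skip: tuple[str, ...] = (),
) -> tuple[FeatureTable, pd.DataFrame, pd.Series | None]:
    """Default chain PQN -> QC-RLSC -> CV filter; stages can be skipped."""
    coeffs = None
    removed = pd.DataFrame(columns=["feature_id", "cv_percent", "reason"])
    if "pqn" not in skip:
        table, coeffs = pqn_normalize(table)
    if "rlsc" not in skip:
        table = qc_rlsc(table, span=loess_span)
    if "cv" not in skip:
        table, removed = cv_filter(table, cutoff_percent=cv_cutoff)
    return table, removed, coeffs
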