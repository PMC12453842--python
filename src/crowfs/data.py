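"""Feature-table data model, delimited-text I/O, z-score normalization, and the
neonatal-EEG feature-name schema.

The central container is :class:`FeatureMatrix`: an ``M x N`` matrix of
numeric feature values with one integer class label per sample.  Labels are
always stored re-encoded to ``0..K-1`` (sorted original order), with the
original-to-code mapping kept for provenance.

Normalization follows a strict train-statistics contract: a
:class:`ZScoreModel` is fit on training data only and then applied, unchanged,
to any split.  Constant training columns are flagged and map to all-zeros
rather than raising, so degenerate synthetic fixtures cannot crash the
pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ZScoreModel",
    "FeatureSchema",
    "read_feature_table",
    "write_feature_table",
    "fit_zscore",
    "apply_zscore",
    "build_eeg_schema",
    "enumerate_feature_names",
    "BIPOLAR_PAIRS",
]


@dataclass
class FeatureMatrix:
    """Samples x features values with integer class labels.

    Parameters
    ----------
    values
        ``(M, N)`` float array; must be finite.
    labels
        ``(M,)`` integer class codes in ``0..K-1``.
    feature_names
        ``N`` unique strings, positionally aligned with the columns.
    sample_ids
        Optional ``M`` strings.
    label_mapping
        Original label -> integer code, recorded when labels were re-encoded.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] | None = None
    label_mapping: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2:
            raise ValueError("need at least 2 samples")
        if n < 1:
            raise ValueError("need at least 1 feature")
        if self.labels.shape != (m,):
            raise ValueError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, "
                f"column '{self.feature_names[bad[1]]}'"
            )
        self.feature_names = [str(s) for s in self.feature_names]
        if len(self.feature_names) != n:
            raise ValueError("feature_names must match the number of columns")
        seen: set[str] = set()
        for name in self.feature_names:
            if name in seen:
                raise ValueError(f"duplicate feature name: '{name}'")
            seen.add(name)
        if self.sample_ids is not None and len(self.sample_ids) != m:
            raise ValueError("sample_ids must match the number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    def subset_features(self, mask_or_indices) -> "FeatureMatrix":
        """New FeatureMatrix restricted to the given columns."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[i] for i in idx],
            sample_ids=None if self.sample_ids is None else list(self.sample_ids),
            label_mapping=self.label_mapping,
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, label_column, self.labels)
        return df


def _detect_sep(path: str) -> str:
    p = str(path).lower()
    return "\t" if p.endswith((".tsv", ".tab")) else ","


def read_feature_table(path, label_column: str = "label") -> FeatureMatrix:
    """Read a delimited table (header row required) into a FeatureMatrix.

    The label column is re-encoded to ``0..K-1`` preserving the sorted order
    of the original label values; feature column order is preserved.  Raises
    ``ValueError`` naming the offender on a missing label column, a duplicate
    feature name, or a non-numeric/missing feature cell.
    """
    sep = _detect_sep(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    if label_column not in header:
        raise ValueError(f"label column '{label_column}' not found in header")
    feat_cols = [c for c in header if c != label_column]
    seen: set[str] = set()
    for c in feat_cols:
        if c in seen:
            raise ValueError(f"duplicate feature name in header: '{c}'")
        seen.add(c)

    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df.columns = header  # undo any pandas dedup-mangling
    raw_labels = df[label_column].to_numpy()
    feats = df[feat_cols]
    values = feats.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric or missing feature value at row {r}, "
            f"column '{feat_cols[c]}'"
        )
    classes, codes = np.unique(raw_labels, return_inverse=True)
    mapping = {_json_safe(k): int(v) for v, k in enumerate(classes)}
    return FeatureMatrix(
        values=values,
        labels=codes,
        feature_names=feat_cols,
        label_mapping=mapping,
    )


def _json_safe(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def write_feature_table(data: FeatureMatrix, path, label_column: str = "label") -> None:
    """Write a FeatureMatrix as CSV (or TSV by extension), full precision."""
    df = data.to_dataframe(label_column)
    df.to_csv(path, sep=_detect_sep(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# z-score normalization with a train-only statistics contract
# ---------------------------------------------------------------------------

@dataclass
class ZScoreModel:
    """Per-feature mean and standard deviation learned from training data.

    ``constant`` flags columns whose training sd is ~0; those columns
    transform to all-zeros.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray
    feature_names: list[str]


def fit_zscore(train: FeatureMatrix) -> ZScoreModel:
    """Fit per-column mean/sd (sample estimator, ddof=1) on training data."""
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    constant = sd <= 1e-12
    safe_sd = np.where(constant, 1.0, sd)
    return ZScoreModel(mean=mean, sd=safe_sd, constant=constant,
                       feature_names=list(train.feature_names))


def apply_zscore(model: ZScoreModel, data: FeatureMatrix) -> FeatureMatrix:
    """Transform ``data`` with TRAINING statistics; never re-fits."""
    if data.feature_names != model.feature_names:
        raise ValueError("feature names do not match the normalization model")
    z = (data.values - model.mean) / model.sd
    z[:, model.constant] = 0.0
    return FeatureMatrix(
        values=z,
        labels=data.labels.copy(),
        feature_names=list(data.feature_names),
        sample_ids=None if data.sample_ids is None else list(data.sample_ids),
        label_mapping=data.label_mapping,
    )


# ---------------------------------------------------------------------------
# Feature-name schema for the 289-feature neonatal EEG table
# ---------------------------------------------------------------------------

#: The 11 bipolar derivations of the neonatal montage.
BIPOLAR_PAIRS = (
    "Fp1-T3", "Fp1-C3", "Fp2-T4", "Fp2-C4", "T3-O1", "T4-O2",
    "C3-P3", "C4-P4", "P3-O1", "P4-O2", "Cz-Pz",
)

_TIME_DOMAIN = ("variance", "zero_crossing")
_WAVELET = tuple(f"wavelet{i}_energy" for i in range(6))
_COMPLEXITY = (
    "app_entropy", "svd_entropy", "samp_entropy", "hjorth_mobility",
    "hjorth_complexity", "hurst_exp", "katz_fd", "higuchi_fd", "decorr_time",
)

_AMPLITUDE = (
    "amplitude_total_power", "amplitude_SD", "amplitude_skew",
    "amplitude_kurtosis", "amplitude_env_mean", "amplitude_env_sd",
    "rEEG_mean", "rEEG_median", "rEEG_lower_margin", "rEEG_upper_margin",
    "rEEG_width", "rEEG_SD", "rEEG_CV", "rEEG_asymmetry",
)
_SPECTRAL = (
    "spectral_power", "spectral_relative_power", "spectral_flatness",
    "spectral_entropy", "spectral_edge_frequency",
)
_CONNECTIVITY = (
    "connectivity_BSI", "connectivity_corr", "connectivity_coh_mean",
    "connectivity_coh_max", "connectivity_coh_freqmax",
)
_SEF_WHOLE = ("spectral_edge_frequency", "fractal_dimension")
_IBI = ("IBI_length_max", "IBI_length_median", "IBI_burst_prc",
        "IBI_burst_number")

#: Band tags: delta 0.5-4, theta 4-7, alpha 7-13, beta 13-30 Hz, whole 0.5-30.
_BAND_TAGS = ("05_4", "4_7", "7_13", "13_30")
_WHOLE_BAND_TAG = "05_30"


@dataclass
class FeatureSchema:
    """Name schema: per-channel feature groups x bipolar pairs, plus
    quantitative-EEG groups x frequency bands.

    ``per_channel_groups`` maps group name -> feature basenames replicated per
    channel pair.  ``qeeg_groups`` maps group name -> (basenames, band tags);
    each basename yields one name per band tag.
    """

    channel_pairs: tuple[str, ...]
    per_channel_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    qeeg_groups: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict)

    @property
    def n_per_channel(self) -> int:
        per_pair = sum(len(g) for g in self.per_channel_groups.values())
        return per_pair * len(self.channel_pairs)

    @property
    def n_qeeg(self) -> int:
        return sum(len(names) * len(tags)
                   for names, tags in self.qeeg_groups.values())

    @property
    def n_total(self) -> int:
        return self.n_per_channel + self.n_qeeg


def build_eeg_schema() -> FeatureSchema:
    """Schema of the 289-feature neonatal EEG table.

    Per channel pair: 2 time-domain + 6 wavelet-energy + 9 complexity features
    over 11 bipolar derivations (187 names); quantitative-EEG: (14 amplitude +
    5 spectral + 5 connectivity) x 4 frequency bands plus 2 whole-band
    spectral and 4 interburst-interval features (102 names).
    """
    return FeatureSchema(
        channel_pairs=BIPOLAR_PAIRS,
        per_channel_groups={
            "time_domain": _TIME_DOMAIN,
            "wavelet_energy": _WAVELET,
            "complexity": _COMPLEXITY,
        },
        qeeg_groups={
            "amplitude": (_AMPLITUDE, _BAND_TAGS),
            "spectral": (_SPECTRAL, _BAND_TAGS),
            "connectivity": (_CONNECTIVITY, _BAND_TAGS),
            "spectral_whole_band": (_SEF_WHOLE, (_WHOLE_BAND_TAG,)),
            "interburst_interval": (_IBI, (_WHOLE_BAND_TAG,)),
        },
    )


def enumerate_feature_names(schema: FeatureSchema) -> list[str]:
    """Deterministic unique names: ``<channelpair>_<feature>`` for per-channel
    groups, ``<feature>_<bandtag>`` for quantitative-EEG groups."""
    names: list[str] = []
    for pair in schema.channel_pairs:
        tag = pair.replace("-", "_")
        for group in schema.per_channel_groups.values():
            names.extend(f"{tag}_{feat}" for feat in group)
    for basenames, band_tags in schema.qeeg_groups.values():
        for feat in basenames:
            names.extend(f"{feat}_{band}" for band in band_tags)
    if len(set(names)) != len(names):
        raise ValueError("schema enumeration produced duplicate names")
    return names
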