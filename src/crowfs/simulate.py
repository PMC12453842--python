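"""Synthetic labeled feature tables with known ground truth.

Generates Gaussian class-conditional data with three kinds of columns —
informative (class-dependent means), redundant (noisy linear combinations of
informative columns), and pure noise — under configurable class imbalance and
label noise.  Every downstream stage (elastic-net screening, KNN fitness,
SVM evaluation) has predictable behavior under this design, which is what
makes quantitative recovery tests possible; no claim of EEG realism is made.

``generate_eeg_shaped`` emulates the *shape* of a graded neonatal-EEG feature
table: 289 named columns over an 11-pair bipolar montage, four ordered
severity classes at an 84:54:12:18 imbalance, with a small planted
informative subset concentrated in temporo-occipital wavelet energies,
beta-band amplitude and delta-band range-EEG statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, build_eeg_schema, enumerate_feature_names

__all__ = ["SyntheticSpec", "generate", "generate_eeg_shaped",
           "EEG_SHAPED_CLASS_COUNTS", "EEG_SHAPED_PLANTED"]

#: Class counts of the emulated neonatal cohort (normal, mild, moderate, major).
EEG_SHAPED_CLASS_COUNTS = (84, 54, 12, 18)

#: Planted informative columns for the EEG-shaped generator, concentrated in a
#: few channel/band groups.
EEG_SHAPED_PLANTED = (
    "T4_O2_wavelet0_energy",
    "T4_O2_wavelet1_energy",
    "T4_O2_wavelet2_energy",
    "T3_O1_wavelet0_energy",
    "Fp2_T4_wavelet1_energy",
    "Fp1_C3_wavelet3_energy",
    "amplitude_SD_13_30",
    "rEEG_median_05_4",
    "rEEG_SD_05_4",
    "IBI_burst_prc_05_30",
)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``effect_size`` is the spacing, in within-class sd units, between the
    means of adjacent ordered classes along each informative column (for two
    classes it is exactly the between-class mean separation).
    ``redundancy_noise`` is the sd of the residual added to the (unit-sd)
    linear combination forming each redundant column.
    """

    n_samples: int = 400
    n_classes: int = 4
    class_proportions: tuple[float, ...] | None = None
    n_informative: int = 10
    n_redundant: int = 20
    n_noise: int = 90
    effect_size: float = 2.0
    redundancy_noise: float = 0.3
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_classes or np.any(p <= 0):
                raise ValueError("class_proportions must be positive, one per class")
            if abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must be in [0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _class_counts(n: int, k: int, proportions, rng) -> np.ndarray:
    p = (np.full(k, 1.0 / k) if proportions is None
         else np.asarray(proportions, dtype=float))
    counts = np.floor(p * n).astype(int)
    # largest-remainder apportionment of the leftover samples
    rem = p * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    if np.any(counts < 1):
        raise ValueError("a class received no samples; increase n_samples")
    return counts


def _labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    counts = _class_counts(spec.n_samples, spec.n_classes,
                           spec.class_proportions, rng)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)
    return labels


def _informative_block(labels, n_cols, effect, n_classes, rng):
    """Each column: unit-sd noise plus a class mean; adjacent class means
    are ``effect`` sd apart, along a random +/-1 direction per column.
    Returns the block and the per-column directions."""
    centered = labels - (n_classes - 1) / 2.0
    signs = rng.choice((-1.0, 1.0), size=n_cols)
    block = rng.standard_normal((labels.size, n_cols))
    block += effect * centered[:, None] * signs[None, :]
    return block, signs


def _redundant_block(informative, signs, n_cols, resid_sd, rng):
    """Noisy positive combinations of sign-aligned informative parents, so
    the class signal of the parents never cancels and each redundant column
    stays strongly correlated with at least one parent."""
    m, n_inf = informative.shape
    aligned = informative * signs[None, :]
    block = np.empty((m, n_cols))
    for j in range(n_cols):
        k = min(2, n_inf)
        parents = rng.choice(n_inf, size=k, replace=False)
        w = rng.uniform(0.5, 1.5, size=k)
        base = aligned[:, parents] @ w
        base = base / max(base.std(), 1e-12)
        block[:, j] = base + resid_sd * rng.standard_normal(m)
    return block


def _flip_labels(labels, rate, n_classes, rng):
    if rate <= 0:
        return labels
    flip = rng.random(labels.size) < rate
    shift = rng.integers(1, n_classes, size=labels.size)
    labels = labels.copy()
    labels[flip] = (labels[flip] + shift[flip]) % n_classes
    return labels


def generate(spec: SyntheticSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Generate a dataset; returns (FeatureMatrix, informative column indices).

    Column positions are shuffled so ground truth is not positional; the
    returned index array locates the informative columns after shuffling.
    """
    if spec.n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    blocks = []
    informative = np.empty((spec.n_samples, 0))
    signs = np.empty(0)
    if spec.n_informative:
        informative, signs = _informative_block(
            labels, spec.n_informative, spec.effect_size, spec.n_classes, rng)
        blocks.append(informative)
    if spec.n_redundant:
        if spec.n_informative == 0:
            raise ValueError("redundant columns require informative parents")
        blocks.append(_redundant_block(informative, signs, spec.n_redundant,
                                       spec.redundancy_noise, rng))
    if spec.n_noise:
        blocks.append(rng.standard_normal((spec.n_samples, spec.n_noise)))
    values = np.concatenate(blocks, axis=1)
    perm = rng.permutation(spec.n_features)
    values = values[:, perm]
    # positions of original informative columns after the shuffle
    inv = np.argsort(perm)
    truth = np.sort(inv[: spec.n_informative])
    labels = _flip_labels(labels, spec.label_noise_rate, spec.n_classes, rng)
    width = max(3, len(str(spec.n_features - 1)))
    names = [f"f{j:0{width}d}" for j in range(spec.n_features)]
    fm = FeatureMatrix(values=values, labels=labels, feature_names=names)
    return fm, truth


def generate_eeg_shaped(
    seed: int,
    effect_size: float = 2.0,
    n_redundant: int = 0,
    redundancy_noise: float = 0.3,
    label_noise_rate: float = 0.0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """289-column table named by the EEG schema, 4 classes at 84:54:12:18.

    Ten informative columns are planted at fixed schema positions
    (:data:`EEG_SHAPED_PLANTED`); ``n_redundant`` further columns correlate
    with them; the rest are noise.  Returns (FeatureMatrix, planted indices).
    """
    rng = np.random.default_rng(seed)
    names = enumerate_feature_names(build_eeg_schema())
    n_features = len(names)
    counts = np.asarray(EEG_SHAPED_CLASS_COUNTS)
    n_samples = int(counts.sum())
    n_classes = counts.size
    labels = np.repeat(np.arange(n_classes), counts)
    rng.shuffle(labels)

    name_to_col = {n: j for j, n in enumerate(names)}
    truth = np.sort([name_to_col[n] for n in EEG_SHAPED_PLANTED])
    values = rng.standard_normal((n_samples, n_features))
    informative, signs = _informative_block(labels, truth.size, effect_size,
                                            n_classes, rng)
    values[:, truth] = informative
    if n_redundant:
        others = np.setdiff1d(np.arange(n_features), truth)
        red_cols = rng.choice(others, size=n_redundant, replace=False)
        values[:, red_cols] = _redundant_block(informative, signs,
                                               n_redundant,
                                               redundancy_noise, rng)
    labels = _flip_labels(labels, label_noise_rate, n_classes, rng)
    fm = FeatureMatrix(values=values, labels=labels, feature_names=names)
    return fm, truth
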