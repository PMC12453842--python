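"""End-to-end two-stage selection: normalize -> elastic-net pre-screen ->
crow search over the retained subspace."""

from __future__ import annotations

import numpy as np

from .data import FeatureMatrix, apply_zscore, fit_zscore
from .fitness import make_context
from .prescreen import ENConfig, ENResult, prescreen
from .search import ICSAConfig, SelectionResult, run_classic_csa, run_icsa

__all__ = ["run_pipeline"]


def run_pipeline(
    train: FeatureMatrix,
    en_config: ENConfig | None = None,
    search_config: ICSAConfig | None = None,
    algorithm: str = "en-icsa",
    w: float = 0.2,
    k_neighbors: int = 5,
    fitness_cv_folds: int = 10,
    awareness: float = 0.1,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[SelectionResult, ENResult]:
    """Run the full selection pipeline on a training table.

    ``algorithm`` is ``"en-icsa"`` (improved search) or ``"csa"`` (classic
    baseline with constant awareness probability).  The returned mask is over
    the original feature axis.  Determinism: the single ``seed`` drives the
    pre-screening CV, the fitness folds, and the search stream.
    """
    if algorithm not in ("en-icsa", "csa"):
        raise ValueError("algorithm must be 'en-icsa' or 'csa'")
    en_config = en_config or ENConfig()
    search_config = search_config or ICSAConfig(seed=seed)
    if normalize:
        train = apply_zscore(fit_zscore(train), train)
    en_result = prescreen(train, en_config, seed=seed)
    retained = en_result.retained_indices
    ctx = make_context(train, retained, w=w, k_neighbors=k_neighbors,
                       cv_folds=fitness_cv_folds, seed=seed)
    kwargs = dict(feature_indices=retained, n_original=train.n_features,
                  feature_names=list(train.feature_names))
    if algorithm == "en-icsa":
        result = run_icsa(ctx, search_config, **kwargs)
    else:
        result = run_classic_csa(ctx, search_config, awareness=awareness,
                                 **kwargs)
    return result, en_result
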