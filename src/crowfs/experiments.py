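"""Desk-scale benchmark protocols.

Two fully self-contained experiments exercise the whole pipeline on
synthetic data with known ground truth:

* the *oracle* problem — ten features, three informative, small enough to
  enumerate every non-empty mask exhaustively, so the exact fitness optimum
  is known and optimizer attainment can be counted;

* the *recovery* problem — a feature table shaped like the graded
  neonatal-EEG cohort (289 named features, four classes at 84:54:12:18)
  with ten planted informative columns, split 70/30, selected on the
  training split, and graded by the fixed-penalty RBF SVM on the held-out
  split.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .data import FeatureMatrix, apply_zscore, fit_zscore
from .evaluate import evaluate_selection
from .fitness import FitnessContext, fitness, make_context
from .pipeline import run_pipeline
from .prescreen import ENConfig
from .search import ICSAConfig, run_classic_csa, run_icsa
from .simulate import SyntheticSpec, generate, generate_eeg_shaped

__all__ = ["build_oracle_context", "enumerate_optimum", "oracle_attainment",
           "recovery_run", "recovery_experiment"]


def build_oracle_context(data_seed: int = 7) -> FitnessContext:
    """Fitness context for the 10-feature enumeration problem
    (3 informative columns, spacing 2 sd, n = 200, four classes)."""
    spec = SyntheticSpec(n_samples=200, n_classes=4, n_informative=3,
                         n_redundant=0, n_noise=7, effect_size=2.0,
                         seed=data_seed)
    fm, _ = generate(spec)
    fmz = apply_zscore(fit_zscore(fm), fm)
    return make_context(fmz, np.arange(fm.n_features), seed=data_seed)


def enumerate_optimum(ctx: FitnessContext):
    """Exhaustive oracle: the best fitness over all 2^L_t - 1 masks."""
    n = ctx.L_t
    best = None
    for bits in range(1, 2 ** n):
        mask = np.array([(bits >> b) & 1 for b in range(n)], dtype=bool)
        f = fitness(ctx, mask)
        if best is None or f.total > best.total:
            best = f
    return best


def oracle_attainment(data_seed: int = 7, n_runs: int = 20,
                      first_seed: int = 0) -> dict:
    """Enumerated optimum vs. ``n_runs`` paired improved/classic searches.

    Returns hit counts against the exact optimum and the mean best fitness
    of both optimizers (the folds, and hence the optimum, are fixed by
    ``data_seed``; only the search streams vary)."""
    ctx = build_oracle_context(data_seed)
    best = enumerate_optimum(ctx)
    icsa_totals, csa_totals = [], []
    hits = 0
    for s in range(first_seed, first_seed + n_runs):
        cfg = ICSAConfig(seed=s)
        r = run_icsa(ctx, cfg)
        icsa_totals.append(r.best_fitness.total)
        hits += abs(r.best_fitness.total - best.total) < 1e-12
        csa_totals.append(
            run_classic_csa(ctx, cfg).best_fitness.total)
    return {
        "optimum": best.total,
        "hits": int(hits),
        "n_runs": int(n_runs),
        "icsa_mean_best": float(np.mean(icsa_totals)),
        "csa_mean_best": float(np.mean(csa_totals)),
        "icsa_totals": icsa_totals,
        "csa_totals": csa_totals,
    }


def recovery_run(data_seed: int, run_seed: int, penalty: float = 0.1) -> dict:
    """One recovery replicate: select on a 70% stratified split of an
    EEG-shaped cohort (fixed-operating-point pre-screening), then grade the
    selected mask and the all-features baseline on the held-out 30%."""
    fm, truth = generate_eeg_shaped(data_seed)
    tr_idx, te_idx = train_test_split(
        np.arange(fm.n_samples), test_size=0.3, stratify=fm.labels,
        random_state=run_seed % (2 ** 31))
    train = FeatureMatrix(fm.values[tr_idx], fm.labels[tr_idx],
                          list(fm.feature_names))
    test = FeatureMatrix(fm.values[te_idx], fm.labels[te_idx],
                         list(fm.feature_names))
    result, en_result = run_pipeline(
        train, en_config=ENConfig(),
        search_config=ICSAConfig(seed=run_seed), seed=run_seed)
    truth_set = set(truth.tolist())
    selected = set(result.selected_indices.tolist())
    rep_sel = evaluate_selection(train, test, result.mask, penalty=penalty,
                                 seed=run_seed)
    rep_all = evaluate_selection(train, test,
                                 np.ones(fm.n_features, dtype=bool),
                                 penalty=penalty, seed=run_seed)
    return {
        "L_t": en_result.L_t,
        "n_selected": result.n_selected,
        "selected_fraction": result.n_selected / result.search_space,
        "planted_recall": len(selected & truth_set) / len(truth_set),
        "f1_selected": rep_sel.weighted["f1"],
        "f1_all": rep_all.weighted["f1"],
    }


def recovery_experiment(n_seeds: int = 10, first_seed: int = 0) -> dict:
    """Aggregate ``n_seeds`` recovery replicates."""
    runs = [recovery_run(1000 + first_seed + i, first_seed + i)
            for i in range(n_seeds)]
    return {
        "runs": runs,
        "recall_mean": float(np.mean([r["planted_recall"] for r in runs])),
        "fraction_mean": float(np.mean([r["selected_fraction"]
                                        for r in runs])),
        "f1_selected_mean": float(np.mean([r["f1_selected"] for r in runs])),
        "f1_all_mean": float(np.mean([r["f1_all"] for r in runs])),
        "strict_wins": int(sum(r["f1_selected"] > r["f1_all"]
                               for r in runs)),
        "bound_holds": int(sum(r["f1_selected"] >= r["f1_all"] - 0.01
                               for r in runs)),
    }
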