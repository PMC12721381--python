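"""End-to-end convenience pipeline: fit per-locus models, build SEEJ count
matrices, and test differential usage across group pairs.

This is the programmatic equivalent of chaining the ``simulate``/``fit``/
``diff`` CLI subcommands, used for cohort-level evaluation where the truth
labels of every group pair are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusage import bh_adjust, lrt_test
from .metrics import filter_expressed_seejs
from .model import SeejAdmixture


@dataclass
class PairTest:
    locus_id: str
    group_a: int
    group_b: int
    differential_truth: bool | None
    pvalue: float
    qvalue: float = np.nan


def fit_cohort(genes, fit_params=None, seed: int = 0) -> list[SeejAdmixture]:
    """Fit one admixture model per cohort gene (joint over all samples)."""
    fit_params = dict(fit_params or {})
    models = []
    for i, cg in enumerate(genes):
        params = dict(k_extra=2, alpha=0.1, eta=1.0, n_iter=300, n_chains=2,
                      random_state=(seed + 7919 * i) % (2 ** 31))
        params.update(fit_params)
        models.append(SeejAdmixture(**params).fit(cg.table))
    return models


def differential_pair_tests(genes, models, pairs, min_reads: int = 10,
                            min_samples: int = 10, n_restarts: int = 1,
                            seed: int = 0) -> list[PairTest]:
    """LRT for every locus and group pair, BH-adjusted across all tests.

    SEEJ counts are filtered to expressed SEEJs (>= ``min_reads`` assigned
    tokens in >= ``min_samples`` samples) before testing; loci with fewer
    than 2 expressed SEEJs for a pair are skipped.
    """
    tests: list[PairTest] = []
    for cg, model in zip(genes, models):
        Y_all = model.seej_count_matrix()
        groups = cg.truth["groups"]
        for pair in pairs:
            a, b = pair["group_a"], pair["group_b"]
            mask = (groups == a) | (groups == b)
            Y = Y_all[mask]
            keep = filter_expressed_seejs(Y, min_reads, min_samples)
            if keep.size < 2:
                continue
            x = (groups[mask] == b).astype(int)
            res = lrt_test(Y[:, keep], x, locus_id=cg.gene.name,
                           n_restarts=n_restarts, seed=seed)
            if np.isfinite(res.pvalue):
                tests.append(PairTest(cg.gene.name, a, b,
                                      pair.get("differential"), res.pvalue))
    q = bh_adjust([t.pvalue for t in tests])
    for t, qv in zip(tests, q):
        t.qvalue = float(qv)
    return tests


def confusion_summary(tests, q_threshold: float = 0.05) -> dict:
    """Sensitivity / specificity / accuracy of q < threshold calls against
    the cohort truth labels."""
    tp = fp = tn = fn = 0
    for t in tests:
        call = t.qvalue < q_threshold
        if t.differential_truth:
            tp += call
            fn += not call
        else:
            fp += call
            tn += not call
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / max(1, tp + tn + fp + fn)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec, "accuracy": acc,
            "n_tests": tp + tn + fp + fn}
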