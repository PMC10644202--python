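"""Cross-validated comparison of genomic prediction methods.

For each trait and each 3:1 training/validation split, a mixed-model GWAS
is run on the training fold only, marker subsets of the k smallest
p-values are formed, and every method is fitted on the training fold and
scored on the validation fold by predictive ability — the Pearson
correlation between observed and predicted values. GBLUP is deterministic
and gets a single replicate; the convolutional nets are excluded at the
full marker set. Cells aggregate by the median over replicates, with a
Wilcoxon signed-rank test of deviation from zero.

No information flows from validation to training: GWAS selection, scaling
parameters and hyperparameter search see training indices only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes, gwas, kernels, ml

__all__ = ["CvPlan", "BenchmarkResult", "make_splits", "predictive_ability",
           "count_models", "deviation_from_zero", "run_benchmark", "ALL_METHODS"]

ALL_METHODS = (
    "gblup", "bayes_a", "bayes_b", "bayes_c", "brr", "bl",
    "rkhs", "rf", "gbdt_a", "gbdt_b", "cnn1d", "cnn2d",
)
_BAYES_FAMILY = {"brr": "BRR", "bayes_a": "BayesA", "bayes_b": "BayesB",
                 "bayes_c": "BayesC", "bl": "BL"}
_CNN_METHODS = ("cnn1d", "cnn2d")
# methods whose inputs are left unscaled: trees entirely; GBLUP and the
# phased CNN skip genotype scaling only
_SKIP_ALL_SCALING = ("rf", "gbdt_a", "gbdt_b")
_SKIP_X_SCALING = ("gblup", "cnn2d")


@dataclass
class CvPlan:
    """Design of the benchmark: splits, replicates, subsets, methods."""

    n_splits: int = 10
    n_model_replicates: int = 10
    subset_sizes: tuple = (48, 96, 192, "all")
    methods: tuple = ALL_METHODS
    traits: tuple = ("D7", "H7")
    seed: int = 0
    n_pcs: int = 4
    mcmc_iter: int = 3000
    mcmc_burn_in: int = 1000
    ml_budget: int = 5
    stratify_by_family: bool = False

    def replicates_for(self, method: str) -> int:
        # GBLUP is deterministic: every replicate would be identical
        return 1 if method == "gblup" else self.n_model_replicates

    def methods_for(self, subset) -> tuple:
        if subset == "all":
            return tuple(m for m in self.methods if m not in _CNN_METHODS)
        return self.methods


@dataclass
class BenchmarkResult:
    """Long-format predictive abilities plus median aggregation."""

    table: pd.DataFrame
    medians: pd.DataFrame
    zero_tests: pd.DataFrame | None = None


def make_splits(n: int, plan: CvPlan):
    """Seeded random 3:1 train/validation partitions (validation =
    ceil(n/4)), all distinct."""
    if n < 8 and plan.n_splits > 1:
        raise ValueError("too few samples for distinct splits")
    if n < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(plan.seed)
    n_val = math.ceil(n / 4)
    seen = set()
    splits = []
    while len(splits) < plan.n_splits:
        perm = rng.permutation(n)
        val = np.sort(perm[:n_val])
        key = tuple(val.tolist())
        if key in seen:
            continue
        seen.add(key)
        splits.append((np.sort(perm[n_val:]), val))
    return splits


def predictive_ability(observed, predicted):
    """Pearson correlation on the validation fold; ``(nan, True)`` when the
    predictions are degenerate (zero variance)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if len(observed) != len(predicted):
        raise ValueError("length mismatch")
    if len(observed) < 3:
        raise ValueError("need at least 3 validation pairs")
    if np.std(predicted) < 1e-12 or np.std(observed) < 1e-12:
        return float("nan"), True
    return float(stats.pearsonr(observed, predicted)[0]), False


def count_models(plan: CvPlan) -> int:
    """Closed-form number of model fits under the replicate/exclusion rules."""
    total = 0
    for subset in plan.subset_sizes:
        for method in plan.methods_for(subset):
            total += plan.replicates_for(method) * plan.n_splits * len(plan.traits)
    return total


def deviation_from_zero(values) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p against zero."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) < 6:
        raise ValueError("need at least 6 replicate values")
    if np.all(v == v[0]):
        raise ValueError("all values identical; the signed-rank test is undefined")
    return float(stats.wilcoxon(v)[1])


def _scale_fit(x):
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _fit_one(method, y_tr_s, X_tr, X_val, phase_tr, phase_val, kernel_cache,
             tr, va, plan, rep_seed):
    """Fit one method on (already scaled) training data, return predictions
    on the standardized scale."""
    if method == "gblup":
        res = kernels.fit_gblup(y_tr_s, kernel_cache["A"], tr, va)
        return res.predictions, res.degenerate
    if method == "rkhs":
        res = kernels.fit_rkhs(y_tr_s, kernel_cache["G"], tr, va,
                               n_iter=plan.mcmc_iter,
                               burn_in=plan.mcmc_burn_in, seed=rep_seed)
        return res.predictions, res.degenerate
    if method in _BAYES_FAMILY:
        spec = bayes.BayesModelSpec(
            family=_BAYES_FAMILY[method], n_iter=plan.mcmc_iter,
            burn_in=plan.mcmc_burn_in, thin=5, seed=rep_seed,
        )
        fit = bayes.fit_bayes(y_tr_s, X_tr, spec)
        return bayes.predict(fit, X_val), False
    if method == "cnn2d":
        space = ml.default_search_spaces(budget=plan.ml_budget)[method]
        preds, _, _ = ml.fit_predict_ml(method, phase_tr, y_tr_s, phase_val,
                                        space, seed=rep_seed)
        return preds, False
    space = ml.default_search_spaces(budget=plan.ml_budget)[method]
    preds, _, _ = ml.fit_predict_ml(method, X_tr, y_tr_s, X_val, space,
                                    seed=rep_seed)
    return preds, False


def run_benchmark(codes, phenotypes, plan: CvPlan, phase=None,
                  loci=None) -> BenchmarkResult:
    """Run the full comparison.

    ``codes``: complete -1/0/1 genotype matrix over the analysis samples;
    ``phenotypes``: DataFrame with one (already spatially adjusted) column
    per trait in ``plan.traits``; ``phase``: optional (n, m, 2) 0/1 layer
    for the phased CNN. Stage errors are recorded per cell and the run
    continues.
    """
    codes = np.asarray(codes, float)
    rows = []
    for trait in plan.traits:
        y_all = phenotypes[trait].to_numpy(float)
        obs = ~np.isnan(y_all)
        y = y_all[obs]
        X = codes[obs]
        ph = phase[obs] if phase is not None else None
        splits = make_splits(len(y), plan)
        for si, (tr, va) in enumerate(splits):
            scan = gwas.mixed_scan(
                y[tr], X[tr], kernels.vanraden_a_matrix(X[tr]),
                n_pcs=min(plan.n_pcs, max(len(tr) - 2, 0)), loci=loci,
            )
            subsets = {}
            for size in plan.subset_sizes:
                if size == "all":
                    subsets[size] = np.arange(X.shape[1])
                else:
                    n_defined = int((~np.isnan(scan.table["p"])).sum())
                    subsets[size] = gwas.select_top_k(scan, min(size, n_defined))
            for size in plan.subset_sizes:
                idx = subsets[size]
                poly_ok, offending = gwas.check_polymorphism(X[tr], idx)
                if not poly_ok:
                    idx = np.array([j for j in idx if j not in set(offending)])
                Xs_tr_raw, Xs_va_raw = X[np.ix_(tr, idx)], X[np.ix_(va, idx)]
                ph_tr = ph[np.ix_(tr, idx)] if ph is not None else None
                ph_va = ph[np.ix_(va, idx)] if ph is not None else None
                # kernels are rebuilt from the subset markers over train +
                # validation samples (the conditioning set)
                cache_t = {}
                if "gblup" in plan.methods_for(size):
                    cache_t["A"] = kernels.vanraden_a_matrix(X[:, idx])
                if "rkhs" in plan.methods_for(size):
                    cache_t["G"] = kernels.gaussian_kernel(X[:, idx], bandwidth=1.0)
                for method in plan.methods_for(size):
                    # training-only scaling
                    if method in _SKIP_ALL_SCALING:
                        y_tr_s, y_mu, y_sd = y[tr], 0.0, 1.0
                        X_tr_s, X_va_s = Xs_tr_raw, Xs_va_raw
                    else:
                        y_mu, y_sd = float(y[tr].mean()), float(y[tr].std()) or 1.0
                        y_tr_s = (y[tr] - y_mu) / y_sd
                        if method in _SKIP_X_SCALING or method in ("rkhs",):
                            X_tr_s, X_va_s = Xs_tr_raw, Xs_va_raw
                        else:
                            mu_x, sd_x = _scale_fit(Xs_tr_raw)
                            X_tr_s = (Xs_tr_raw - mu_x) / sd_x
                            X_va_s = (Xs_va_raw - mu_x) / sd_x
                    for rep in range(plan.replicates_for(method)):
                        method_tag = ALL_METHODS.index(method) if method in ALL_METHODS else 99
                        rep_seed = (plan.seed + 100_000 * si + 1000 * rep
                                    + 13 * method_tag) % (2**31)
                        try:
                            preds_s, degen = _fit_one(
                                method, y_tr_s, X_tr_s, X_va_s, ph_tr, ph_va,
                                cache_t, tr, va, plan, rep_seed,
                            )
                            preds = preds_s * y_sd + y_mu
                            r, degen2 = predictive_ability(y[va], preds)
                            rows.append((trait, method, str(size), si, rep, r,
                                         degen or degen2, ""))
                        except Exception as exc:  # record and continue
                            rows.append((trait, method, str(size), si, rep,
                                         np.nan, True, f"{type(exc).__name__}: {exc}"))
    table = pd.DataFrame(rows, columns=["trait", "method", "subset", "split",
                                        "replicate", "r", "degenerate", "error"])
    medians = (
        table.groupby(["trait", "method", "subset"])["r"]
        .median()
        .reset_index()
        .rename(columns={"r": "median_r"})
    )
    ztests = []
    for key, sub in table.groupby(["trait", "method", "subset"]):
        vals = sub["r"].to_numpy()
        try:
            p = deviation_from_zero(vals)
        except ValueError:
            p = np.nan
        ztests.append((*key, p))
    zero_tests = pd.DataFrame(ztests, columns=["trait", "method", "subset", "p_zero"])
    return BenchmarkResult(table=table, medians=medians, zero_tests=zero_tests)
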