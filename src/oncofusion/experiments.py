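"""End-to-end benchmark experiments on synthetic cohorts.

Each function runs one self-contained study on generated data — GA-vs-
enumeration optimality, class balance of GA splits, outlier capture by the
out-of-distribution mode, the three-split difficulty ordering, fusion vs.
single-modality prediction, and MIL signal recovery — and returns the
measured quantities.  All randomness derives from the single ``seed``
argument.  Problem sizes (cohorts of 200/600 patients, 10 replicate
seeds, GA populations of 150–300 with early stopping, 150-tree forests)
are chosen so a full run completes in minutes on one CPU while leaving
each effect clearly measurable.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._utils import child_seed
from .gasplit import (
    GAParams,
    SplitProblem,
    exhaustive_split_oracle,
    problem_from_vectors,
    run_ga,
)
from .mil import Bag, MILParams, attend, predict_bags, train_mil
from .predict import (
    ModelConfig,
    build_recurrence_labels,
    build_survival_labels,
    evaluate_protocol,
    fit_predict,
    site_holdout_split,
)
from .simulate import SimConfig, SyntheticEmbeddingSource, generate_cohort, plant_outliers
from .vectorize import assemble_vectors

__all__ = [
    "ga_oracle_equivalence",
    "class_balance_experiment",
    "outlier_capture_experiment",
    "split_ordering_experiment",
    "fusion_experiment",
    "mil_recovery_experiment",
    "mil_complementary_experiment",
]

_GA_SMALL = dict(population_size=300, stagnation_limit=40, max_generations=500,
                 mutation_rate=0.3)
_GA_COHORT = dict(population_size=150, stagnation_limit=15, max_generations=120,
                  mutation_rate=0.3)
_GA_OUTLIER = dict(population_size=300, stagnation_limit=30, max_generations=300,
                   mutation_rate=0.3)


def _task_labels(cohort, vectors) -> np.ndarray:
    rec = build_recurrence_labels(cohort)
    sur = build_survival_labels(cohort)
    return np.column_stack([rec.label_array(vectors.patient_ids),
                            sur.label_array(vectors.patient_ids)])


def ga_oracle_equivalence(seed: int, n_instances: int = 20) -> dict:
    """Fraction of random small instances where the GA attains the
    enumeration optimum, over both fitness modes and two instance shapes
    (n=10 eligible with N=2 of 45 masks; n=12 with N=3 of 220 masks)."""
    rng = np.random.default_rng(child_seed(seed, "oracle-instances"))
    total = matched = 0
    for i in range(n_instances):
        for n, n_test in ((10, 2), (12, 3)):
            X = rng.normal(size=(n, 6))
            labels = rng.integers(0, 2, size=(n, 2)).astype(float)
            for mode in ("in_distribution", "out_of_distribution"):
                prob = SplitProblem(X=X, patient_ids=[f"{j:02d}" for j in range(n)],
                                    labels=labels, test_fraction=n_test / n, mode=mode)
                _, f_opt = exhaustive_split_oracle(prob, n_test)
                res = run_ga(prob, GAParams(seed=child_seed(seed, "oracle-ga", i, n, mode),
                                            **_GA_SMALL))
                matched += bool(np.isclose(res.best_fitness, f_opt, atol=1e-9))
                total += 1
    return {"match_rate": 100.0 * matched / total, "n": total}


def class_balance_experiment(seed: int, n_cohorts: int = 3,
                             n_patients: int = 200) -> dict:
    """Largest class-distribution deviation of GA test sets, relative to the
    1/N + 0.02 balance bound, with the mode-scaled default alpha."""
    worst_ratio = 0.0
    worst_dev = 0.0
    for c in range(n_cohorts):
        cohort = generate_cohort(SimConfig(n_patients=n_patients,
                                           seed=child_seed(seed, "balance-cohort", c)))
        vs = assemble_vectors(cohort)
        labels = _task_labels(cohort, vs)
        for mode in ("in_distribution", "out_of_distribution"):
            prob = problem_from_vectors(vs, labels, mode=mode)
            res = run_ga(prob, GAParams(seed=child_seed(seed, "balance-ga", c, mode),
                                        **_GA_COHORT))
            in_test = np.isin(vs.patient_ids, res.test_ids)
            bound = 1.0 / in_test.sum() + 0.02
            for k in range(labels.shape[1]):
                lab = labels[:, k]
                obs = ~np.isnan(lab)
                dev = abs(lab[obs & in_test].mean() - lab[obs].mean())
                worst_dev = max(worst_dev, dev)
                worst_ratio = max(worst_ratio, dev / bound)
    return {"max_deviation": worst_dev, "max_deviation_over_bound": worst_ratio,
            "n": n_cohorts * 2}


def outlier_capture_experiment(seed: int, n_seeds: int = 10, n_patients: int = 200,
                               k: int = 10, scale: float = 5.0) -> dict:
    """How many of k planted outliers the out-of-distribution split captures.

    The cohort is generated without missingness so every planted patient is
    eligible for the test set (incomplete vectors go to training by rule).
    """
    captured = []
    for m in range(n_seeds):
        cohort = generate_cohort(SimConfig(n_patients=n_patients, missing_rates={},
                                           seed=child_seed(seed, "outlier-cohort", m)))
        cohort, ids = plant_outliers(cohort, k=k, scale=scale,
                                     seed=child_seed(seed, "outlier-plant", m))
        vs = assemble_vectors(cohort)
        labels = _task_labels(cohort, vs)
        prob = problem_from_vectors(vs, labels, mode="out_of_distribution")
        res = run_ga(prob, GAParams(seed=child_seed(seed, "outlier-ga", m),
                                    **_GA_OUTLIER))
        captured.append(len(set(ids) & set(res.test_ids)))
    return {"captured": captured,
            "seeds_with_at_least_8": sum(c >= 8 for c in captured),
            "n": n_seeds}


def split_ordering_experiment(seed: int, n_seeds: int = 10, n_patients: int = 600,
                              repeats: int = 5) -> dict:
    """Mean RF AUC per split regime; counts seeds with in >= out >= site.

    Per replicate: one synthetic cohort, GA in/out splits plus the
    oropharynx site holdout, both prediction tasks evaluated with
    ``repeats`` seeded forests each; the per-regime score is the mean AUC
    over tasks and repeats.
    """
    per_seed = []
    ok = 0
    for m in range(n_seeds):
        cohort = generate_cohort(SimConfig(n_patients=n_patients,
                                           seed=child_seed(seed, "ordering-cohort", m)))
        vs = assemble_vectors(cohort)
        labels = _task_labels(cohort, vs)
        splits = {}
        for mode, key in (("in_distribution", "in"), ("out_of_distribution", "out")):
            prob = problem_from_vectors(vs, labels, mode=mode)
            splits[key] = run_ga(prob, GAParams(seed=child_seed(seed, "ordering-ga", m, mode),
                                                **_GA_COHORT))
        splits["site"] = site_holdout_split(cohort, "oropharynx")
        rep = evaluate_protocol(cohort, splits, tasks=("recurrence", "survival"),
                                repeats=repeats, seed=child_seed(seed, "ordering-eval", m),
                                config=ModelConfig(n_estimators=150))
        aucs = {key: float(np.mean([rep[(key, t)].mean_auc
                                    for t in ("recurrence", "survival")]))
                for key in splits}
        ok += aucs["in"] >= aucs["out"] >= aucs["site"]
        per_seed.append(aucs)
    return {"per_seed": per_seed,
            "mean_auc_in": float(np.mean([a["in"] for a in per_seed])),
            "mean_auc_out": float(np.mean([a["out"] for a in per_seed])),
            "mean_auc_site": float(np.mean([a["site"] for a in per_seed])),
            "seeds_ordered": ok, "n": n_seeds}


_MODALITY_SETS = {"all": None,
                  "clinical": ("clinical_pathological",),
                  "blood": ("blood",),
                  "icd": ("icd",),
                  "tma": ("tma",)}


def fusion_experiment(seed: int, n_seeds: int = 10, n_patients: int = 600) -> dict:
    """All-modality vs single-modality recurrence AUC on cohorts whose
    planted signal is distributed across modalities."""
    per_seed = []
    wins = 0
    for m in range(n_seeds):
        cohort = generate_cohort(SimConfig(n_patients=n_patients,
                                           seed=child_seed(seed, "fusion-cohort", m)))
        labels = build_recurrence_labels(cohort)
        sub = cohort.subset(labels.included_ids())
        y = labels.label_array(sub.patient_ids)
        tr_ids, te_ids = train_test_split(
            sub.patient_ids, test_size=0.25, stratify=y,
            random_state=child_seed(seed, "fusion-split", m) % (2**32))
        train, test = sub.subset(tr_ids), sub.subset(te_ids)
        y_tr = labels.label_array(train.patient_ids).astype(int)
        y_te = labels.label_array(test.patient_ids).astype(int)
        aucs = {}
        for name, mods in _MODALITY_SETS.items():
            scores = fit_predict(train, y_tr, test,
                                 config=ModelConfig(n_estimators=150, modalities=mods),
                                 seed=child_seed(seed, "fusion-fit", m, name))
            aucs[name] = float(roc_auc_score(y_te, scores))
        wins += all(aucs["all"] > aucs[k] for k in ("clinical", "blood", "icd", "tma"))
        per_seed.append(aucs)
    return {"per_seed": per_seed,
            "mean_auc_all": float(np.mean([a["all"] for a in per_seed])),
            "mean_auc_best_single": float(np.mean(
                [max(a[k] for k in ("clinical", "blood", "icd", "tma"))
                 for a in per_seed])),
            "seeds_fusion_wins": wins, "n": n_seeds}


def _planted_bags(labels: dict[str, int], src: SyntheticEmbeddingSource,
                  sources: tuple[str, ...], n_per_source: int) -> list[Bag]:
    bags = []
    for pid, y in labels.items():
        parts, tags, infos = [], [], []
        for s in sources:
            emb, info = src.instances(pid, s, n_per_source)
            parts.append(emb)
            infos.append(info)
            tags += [s] * n_per_source
        bags.append(Bag(pid, np.vstack(parts), tags, label=y,
                        informative=np.concatenate(infos)))
    return bags


def mil_recovery_experiment(seed: int, n_bags: int = 200, bag_size: int = 48) -> dict:
    """Held-out bag AUC and attention concentration on planted instances."""
    labels = {f"{i:04d}": int(i < n_bags // 2) for i in range(n_bags)}
    src = SyntheticEmbeddingSource(labels, embed_dim=64,
                                   informative_sources=("WSI",),
                                   seed=child_seed(seed, "milrec-embed"))
    bags = _planted_bags(labels, src, ("WSI",), bag_size)
    rng = np.random.default_rng(child_seed(seed, "milrec-split"))
    idx = rng.permutation(n_bags)
    train = [bags[i] for i in idx[:int(0.75 * n_bags)]]
    test = [bags[i] for i in idx[int(0.75 * n_bags):]]
    model = train_mil(train, MILParams(seed=child_seed(seed, "milrec-train")))
    y = np.array([b.label for b in test])
    auc = float(roc_auc_score(y, predict_bags(model, test)))
    ratios = []
    for bag in test:
        if bag.label == 1 and bag.informative is not None and bag.informative.any():
            res = attend(model, bag)
            ratios.append(res.weights[bag.informative].mean() * bag.n_instances)
    return {"held_out_auc": auc,
            "attention_ratio_vs_uniform": float(np.mean(ratios)),
            "n": n_bags}


def mil_complementary_experiment(seed: int, n_seeds: int = 10, n_bags: int = 300,
                                 n_per_source: int = 32) -> dict:
    """Combined WSI+TMA bags vs single-source bags with complementary signal.

    Half the positive patients carry signal only in WSI tiles, half only in
    the CD8-stained TMA tiles, so either source alone can detect only half
    the positive class while the combined bags see all of it.  A 5-member
    restart ensemble matters here: single restarts of the combined model
    sometimes latch onto only one signal direction, while independently
    initialized members tend to cover both.
    """
    wins = 0
    per_seed = []
    for m in range(n_seeds):
        labels = {f"{i:04d}": int(i < n_bags // 2) for i in range(n_bags)}
        pos = [p for p, y in labels.items() if y == 1]
        pps = {p: (("WSI",) if i % 2 == 0 else ("TMA:CD8",))
               for i, p in enumerate(pos)}
        src = SyntheticEmbeddingSource(
            labels, embed_dim=64, informative_fraction=0.15,
            seed=child_seed(seed, "milcomp-embed", m), per_patient_sources=pps)
        rng = np.random.default_rng(child_seed(seed, "milcomp-split", m))
        idx = rng.permutation(n_bags)
        n_train = int(0.6 * n_bags)
        itr, ite = idx[:n_train], idx[n_train:]
        aucs = {}
        for name, sources in (("wsi", ("WSI",)), ("tma", ("TMA:CD8",)),
                              ("both", ("WSI", "TMA:CD8"))):
            bags = _planted_bags(labels, src, sources, n_per_source)
            train = [bags[i] for i in itr]
            test = [bags[i] for i in ite]
            model = train_mil(train, MILParams(
                epochs=60, restarts=5,
                seed=child_seed(seed, "milcomp-train", m, name)))
            y = np.array([b.label for b in test])
            aucs[name] = float(roc_auc_score(y, predict_bags(model, test)))
        wins += aucs["both"] > aucs["wsi"] and aucs["both"] > aucs["tma"]
        per_seed.append(aucs)
    return {"per_seed": per_seed, "seeds_combined_wins": wins, "n": n_seeds}
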