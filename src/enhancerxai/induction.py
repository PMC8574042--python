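"""Evolutionary induction of a constrained fuzzy rule base.

The search is a seeded, elitist genetic algorithm over variable-length
rule lists.  Hard explainability constraints (at most 50 rules, at most
3 antecedents per rule) are enforced by repair, the fitness is a
weighted scalarization of balanced accuracy minus parsimony penalties,
and rule dominance (confidence x support on the training data, scaled
to [0, 10]) weights each rule at inference time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .fuzzy import (
    CLASSES,
    ENHANCER,
    LABELS,
    MAX_ANTECEDENTS,
    MAX_RULES,
    NON_ENHANCER,
    FuzzyPartition,
    FuzzyRule,
    RuleBase,
    infer_matrix,
    partition_from_centers,
)
from .tracks import BinDataset


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------


@dataclass
class InductionConfig:
    max_rules: int = MAX_RULES
    max_antecedents: int = MAX_ANTECEDENTS
    population_size: int = 80
    generations: int = 120
    crossover_rate: float = 0.7
    mutation_rate: float = 0.9
    w_accuracy: float = 1.0
    w_rules: float = 0.004
    w_antecedents: float = 0.001
    partition_overlap: float = 0.25
    partition_fou: float = 0.05
    partition_jitter_rate: float = 0.05
    partition_jitter_sd: float = 0.02
    init_rules: tuple[int, int] = (3, 10)
    elitism: int = 2
    early_stop_generations: int = 30
    early_stop_tolerance: float = 1e-4
    # balanced accuracy is averaged over these probability thresholds so the
    # learned base is also calibrated for the stricter region-calling cutoff
    fitness_thresholds: tuple[float, ...] = (0.5, 0.8)
    # smoothing prior toward the default probability (see RuleBase); keeps
    # weak unopposed rule firing from saturating the probability at 1
    default_weight: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rules < 2:
            raise ValueError("max_rules must be >= 2")
        if not 1 <= self.max_antecedents <= MAX_ANTECEDENTS:
            raise ValueError(f"max_antecedents must be in 1..{MAX_ANTECEDENTS}")
        for name in ("crossover_rate", "mutation_rate", "partition_jitter_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    average_recall: float
    auc: float
    gini: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "average_recall": self.average_recall,
            "auc": self.auc,
            "gini": self.gini,
        }


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------


def initialize_partitions(
    dataset: BinDataset,
    overlap: float = 0.25,
    fou: float = 0.05,
) -> dict[str, FuzzyPartition]:
    """Quantile-anchored three-set partitions: low/medium/high centered at
    the empirical Q25/Q50/Q75 of each normalized mark.  Constant marks are
    excluded (with a warning) since they carry no information."""
    partitions: dict[str, FuzzyPartition] = {}
    excluded = []
    for j, mark in enumerate(dataset.feature_order):
        v = dataset.X[:, j]
        q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75])
        # keep centers strictly ordered inside [0, 1]
        eps = 1e-3
        c1 = float(np.clip(q25, eps, 1 - 3 * eps))
        c2 = float(np.clip(q50, c1 + eps, 1 - 2 * eps))
        c3 = float(np.clip(q75, c2 + eps, 1 - eps))
        if v.max() - v.min() < 1e-12:
            excluded.append(mark)
            continue
        partitions[mark] = partition_from_centers(
            mark, (c1, c2, c3), overlap=overlap, fou=fou
        )
    if excluded:
        warnings.warn(f"constant marks excluded from rule search: {excluded}")
    if not partitions:
        raise ValueError("no informative marks: all features are constant")
    return partitions


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(y_pred & y_true)),
        tn=int(np.sum(~y_pred & ~y_true)),
        fp=int(np.sum(y_pred & ~y_true)),
        fn=int(np.sum(~y_pred & y_true)),
    )


def metrics_from_confusion(cm: ConfusionMatrix, auc: float) -> EvaluationReport:
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    recall_neg = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return EvaluationReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        average_recall=0.5 * (recall + recall_neg),
        auc=auc,
        gini=2.0 * auc - 1.0,
    )


def evaluate(
    rulebase: RuleBase,
    dataset: BinDataset,
    threshold: float = 0.5,
) -> tuple[ConfusionMatrix, EvaluationReport]:
    """Threshold per-bin probabilities into classes and compute accuracy,
    precision, recall, average recall, AUC (rank statistic) and gini
    (2*AUC - 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    probs = infer_matrix(rulebase, dataset.X, dataset.feature_order)
    y = dataset.y
    # strict > so bins where nothing fires (default probability 0.5) fall
    # to the default class at the standard 0.5 threshold
    cm = confusion_from_predictions(y, probs > threshold)
    if y.all() or not y.any():
        raise ValueError("AUC requires both classes in the dataset")
    auc = float(roc_auc_score(y.astype(int), probs))
    return cm, metrics_from_confusion(cm, auc)


def cross_cell_apply(rulebase: RuleBase, dataset: BinDataset) -> np.ndarray:
    """Pure inference of a trained rule base on another dataset (e.g. a
    different cell line); no refitting.  Extra marks are ignored with a
    warning, missing rule-referenced marks raise."""
    needed = rulebase.marks
    missing = [m for m in needed if m not in dataset.feature_order]
    if missing:
        raise KeyError(f"dataset lacks marks required by rules: {missing}")
    extra = [m for m in dataset.feature_order if m not in rulebase.partitions]
    if extra:
        warnings.warn(f"marks not referenced by the model ignored: {extra}")
    return infer_matrix(rulebase, dataset.X, dataset.feature_order)


# ---------------------------------------------------------------------------
# genetic search
# ---------------------------------------------------------------------------

Gene = tuple[tuple[tuple[str, str], ...], str]  # (sorted antecedents, consequent)


class _Inducer:
    """Internal GA state: caches rule firings and dominances so candidate
    evaluation is a handful of vector adds per individual."""

    def __init__(self, train: BinDataset, config: InductionConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.y = train.y.astype(bool)
        if self.y.all() or not self.y.any():
            raise ValueError("training data must contain both classes")
        self.n = train.n_bins
        self.base_partitions = initialize_partitions(
            train, config.partition_overlap, config.partition_fou
        )
        self.marks = list(self.base_partitions)
        self.X = train.X
        self.col = {m: i for i, m in enumerate(train.feature_order)}
        self._memb: dict = {}
        self._firing: dict = {}
        self.n_pos = int(self.y.sum())
        self.n_neg = self.n - self.n_pos

    # -- caches -------------------------------------------------------------

    def _membership(self, mark, label, partitions):
        part = partitions[mark]
        key = (mark, label, part.fingerprint())
        hit = self._memb.get(key)
        if hit is None:
            if len(self._memb) > 4096:
                self._memb.clear()
            fset = part.sets[label]
            x = np.clip(self.X[:, self.col[mark]], 0.0, 1.0)
            hit = (fset.lower(x), fset.upper(x))
            self._memb[key] = hit
        return hit

    def firing(self, ants, partitions, pfp):
        key = (ants, pfp)
        hit = self._firing.get(key)
        if hit is None:
            if len(self._firing) > 8192:
                self._firing.clear()
            f_lo = f_up = None
            for mark, lab in ants:
                mlo, mup = self._membership(mark, lab, partitions)
                f_lo = mlo if f_lo is None else np.minimum(f_lo, mlo)
                f_up = mup if f_up is None else np.minimum(f_up, mup)
            mid = 0.5 * (f_lo + f_up)
            dom = {}
            s_total = float(mid.sum())
            s_pos = float(mid[self.y].sum())
            # support is class-relative so minority-class rules are not
            # drowned by the enhancer:background imbalance
            for cls, s_match, n_cls in (
                (ENHANCER, s_pos, self.n_pos),
                (NON_ENHANCER, s_total - s_pos, self.n_neg),
            ):
                if s_total > 0 and n_cls > 0:
                    dom[cls] = 10.0 * (s_match / s_total) * (s_match / n_cls)
                else:
                    dom[cls] = 0.0
                dom[cls] = min(dom[cls], 10.0)
            hit = (f_lo, f_up, dom)
            self._firing[key] = hit
        return hit

    # -- genes --------------------------------------------------------------

    def heuristic_gene(self, consequent: str | None = None) -> Gene:
        """Covering-style rule built from one training bin: the bin's best
        linguistic label on 1..max_antecedents random marks, with the
        bin's class as consequent."""
        if consequent is None:
            # draw the seeding class uniformly so minority-class rules are
            # proposed as often as majority ones
            consequent = ENHANCER if self.rng.random() < 0.5 else NON_ENHANCER
        pool = np.flatnonzero(self.y if consequent == ENHANCER else ~self.y)
        i = int(pool[self.rng.integers(len(pool))])
        k = int(self.rng.integers(1, self.config.max_antecedents + 1))
        k = min(k, len(self.marks))
        which = self.rng.choice(len(self.marks), size=k, replace=False)
        ants = []
        for m in which:
            mark = self.marks[m]
            label = self.base_partitions[mark].best_label(
                float(np.clip(self.X[i, self.col[mark]], 0.0, 1.0))
            )
            ants.append((mark, label))
        return (tuple(sorted(ants)), consequent)

    def random_individual(self) -> list[Gene]:
        lo, hi = self.config.init_rules
        n_rules = int(self.rng.integers(lo, hi + 1))
        rules = [self.heuristic_gene() for _ in range(n_rules)]
        return self.repair(rules)

    # -- constraint repair --------------------------------------------------

    def repair(self, rules: list[Gene]) -> list[Gene]:
        seen = set()
        out: list[Gene] = []
        for ants, cls in rules:
            ants = ants[: self.config.max_antecedents]
            gene = (tuple(sorted(ants)), cls)
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
        out = out[: self.config.max_rules]
        present = {cls for _, cls in out}
        for cls in CLASSES:
            if cls not in present:
                gene = self.heuristic_gene(cls)
                if len(out) >= self.config.max_rules:
                    out.pop()
                out.append(gene)
        return out

    # -- fitness ------------------------------------------------------------

    def probabilities(self, rules: list[Gene], partitions, pfp) -> np.ndarray:
        agg_lo = {c: np.zeros(self.n) for c in CLASSES}
        agg_up = {c: np.zeros(self.n) for c in CLASSES}
        for ants, cls in rules:
            f_lo, f_up, dom = self.firing(ants, partitions, pfp)
            w = dom[cls]
            if w == 0.0:
                continue
            agg_lo[cls] += w * f_lo
            agg_up[cls] += w * f_up
        mid_e = 0.5 * (agg_lo[ENHANCER] + agg_up[ENHANCER])
        mid_n = 0.5 * (agg_lo[NON_ENHANCER] + agg_up[NON_ENHANCER])
        w0 = self.config.default_weight
        denom = mid_e + mid_n + w0
        probs = np.full(self.n, 0.5)
        nz = denom > 0
        probs[nz] = (mid_e[nz] + 0.5 * w0) / denom[nz]
        return probs

    def fitness(self, rules: list[Gene], partitions, pfp) -> float:
        probs = self.probabilities(rules, partitions, pfp)
        bas = []
        for thr in self.config.fitness_thresholds:
            pred = probs > thr
            tpr = np.sum(pred & self.y) / self.n_pos
            tnr = np.sum(~pred & ~self.y) / self.n_neg
            bas.append(0.5 * (tpr + tnr))
        ba = float(np.mean(bas))
        n_ants = sum(len(ants) for ants, _ in rules)
        return (
            self.config.w_accuracy * ba
            - self.config.w_rules * len(rules)
            - self.config.w_antecedents * n_ants
        )

    # -- variation ----------------------------------------------------------

    def mutate(self, rules: list[Gene]) -> list[Gene]:
        rng = self.rng
        rules = list(rules)
        op = rng.random()
        if op < 0.25 and len(rules) < self.config.max_rules:
            rules.append(self.heuristic_gene())
        elif op < 0.45 and len(rules) > 2:
            rules.pop(int(rng.integers(len(rules))))
        elif op < 0.9 and rules:
            i = int(rng.integers(len(rules)))
            ants, cls = rules[i]
            ants = list(ants)
            what = rng.random()
            if what < 0.4:  # relabel one antecedent
                j = int(rng.integers(len(ants)))
                mark, _ = ants[j]
                ants[j] = (mark, LABELS[int(rng.integers(3))])
            elif what < 0.7:  # swap one antecedent mark
                j = int(rng.integers(len(ants)))
                mark = self.marks[int(rng.integers(len(self.marks)))]
                ants[j] = (mark, ants[j][1])
            elif what < 0.85 and len(ants) < self.config.max_antecedents:
                used = {m for m, _ in ants}
                free = [m for m in self.marks if m not in used]
                if free:
                    mark = free[int(rng.integers(len(free)))]
                    ants.append((mark, LABELS[int(rng.integers(3))]))
            elif len(ants) > 1:
                ants.pop(int(rng.integers(len(ants))))
            # drop duplicate marks that a swap may have produced
            dedup: dict[str, str] = {}
            for mark, lab in ants:
                dedup.setdefault(mark, lab)
            rules[i] = (tuple(sorted(dedup.items())), cls)
        elif rules:  # flip consequent
            i = int(rng.integers(len(rules)))
            ants, cls = rules[i]
            rules[i] = (ants, NON_ENHANCER if cls == ENHANCER else ENHANCER)
        return rules

    def jitter_partitions(self, partitions: dict[str, FuzzyPartition]):
        """Copy the partitions with one mark's centers jittered."""
        rng = self.rng
        mark = self.marks[int(rng.integers(len(self.marks)))]
        part = partitions[mark]
        centers = [part.sets[lab].center for lab in LABELS]
        centers = np.clip(
            np.array(centers) + rng.normal(0, self.config.partition_jitter_sd, 3),
            1e-3,
            1 - 1e-3,
        )
        centers.sort()
        if centers[0] + 1e-3 >= centers[1] or centers[1] + 1e-3 >= centers[2]:
            return partitions  # degenerate jitter; keep as-is
        new = dict(partitions)
        try:
            new[mark] = partition_from_centers(
                mark,
                tuple(centers),
                overlap=self.config.partition_overlap,
                fou=self.config.partition_fou,
            )
        except ValueError:
            return partitions
        return new

    def crossover(self, a: list[Gene], b: list[Gene]):
        rng = self.rng
        ia = int(rng.integers(1, len(a) + 1))
        ib = int(rng.integers(1, len(b) + 1))
        return a[:ia] + b[ib:], b[:ib] + a[ia:]

    # -- main loop ----------------------------------------------------------

    def run(self) -> RuleBase:
        cfg = self.config
        base_fp = tuple(sorted((m, p.fingerprint()) for m, p in self.base_partitions.items()))

        def pfp_of(partitions):
            if partitions is self.base_partitions:
                return base_fp
            return tuple(sorted((m, p.fingerprint()) for m, p in partitions.items()))

        pop = [
            (self.random_individual(), self.base_partitions)
            for _ in range(cfg.population_size)
        ]
        fits = [
            self.fitness(rules, parts, pfp_of(parts)) for rules, parts in pop
        ]
        best_hist: list[float] = []
        self.best_history = best_hist  # exposed for the elitism invariant
        for gen in range(cfg.generations):
            order = np.argsort(fits)[::-1]
            elite = [pop[i] for i in order[: cfg.elitism]]
            elite_fits = [fits[i] for i in order[: cfg.elitism]]
            best_hist.append(elite_fits[0])
            if (
                len(best_hist) > cfg.early_stop_generations
                and best_hist[-1] - best_hist[-1 - cfg.early_stop_generations]
                < cfg.early_stop_tolerance
            ):
                break
            new_pop = list(elite)
            new_fits = list(elite_fits)
            while len(new_pop) < cfg.population_size:
                pa = self.tournament(fits)
                pb = self.tournament(fits)
                rules_a, parts_a = pop[pa]
                rules_b, parts_b = pop[pb]
                child_rules = list(rules_a)
                child_parts = parts_a
                if self.rng.random() < cfg.crossover_rate:
                    child_rules, _ = self.crossover(list(rules_a), list(rules_b))
                if self.rng.random() < cfg.mutation_rate:
                    child_rules = self.mutate(child_rules)
                if self.rng.random() < cfg.partition_jitter_rate:
                    child_parts = self.jitter_partitions(child_parts)
                child_rules = self.repair(child_rules)
                new_pop.append((child_rules, child_parts))
                new_fits.append(
                    self.fitness(child_rules, child_parts, pfp_of(child_parts))
                )
            pop, fits = new_pop, new_fits
        best_i = int(np.argmax(fits))
        rules, partitions = pop[best_i]
        return self.finalize(rules, partitions, pfp_of(partitions))

    def tournament(self, fits, k: int = 3) -> int:
        idx = self.rng.integers(0, len(fits), size=k)
        return int(max(idx, key=lambda i: fits[i]))

    def finalize(self, rules: list[Gene], partitions, pfp) -> RuleBase:
        out_rules = []
        for ants, cls in rules:
            _, _, dom = self.firing(ants, partitions, pfp)
            out_rules.append(FuzzyRule(ants, cls, dom[cls]))
        # drop inert rules but keep at least one per class
        kept = [r for r in out_rules if r.dominance > 0]
        for cls in CLASSES:
            if not any(r.consequent == cls for r in kept):
                candidates = [r for r in out_rules if r.consequent == cls]
                kept.append(max(candidates, key=lambda r: r.dominance))
        kept.sort(key=lambda r: (-r.dominance, r.signature()))
        rb = RuleBase(kept, dict(partitions), default_weight=self.config.default_weight)
        rb.validate_trained()
        return rb


def induce_rulebase(train: BinDataset, config: InductionConfig) -> RuleBase:
    """Learn a constrained rule base from a labeled bin dataset.

    Deterministic for a fixed ``config.seed`` and training data.
    """
    return _Inducer(train, config).run()


def compute_dominance(
    rule: FuzzyRule, rulebase: RuleBase, train: BinDataset
) -> float:
    """Dominance = confidence x support of the rule on the training data,
    scaled to [0, 10]."""
    col = {m: i for i, m in enumerate(train.feature_order)}
    f = None
    for mark, lab in rule.antecedents:
        if mark not in col:
            raise KeyError(f"training data lacks mark {mark!r}")
        fset = rulebase.partitions[mark].sets[lab]
        x = np.clip(train.X[:, col[mark]], 0.0, 1.0)
        lo, up = fset.lower(x), fset.upper(x)
        mid = 0.5 * (lo + up)
        f = mid if f is None else np.minimum(f, mid)
    match = train.y if rule.consequent == ENHANCER else ~train.y
    s_total = float(f.sum())
    n_cls = int(match.sum())
    if s_total == 0 or n_cls == 0:
        return 0.0
    s_match = float(f[match].sum())
    return min(10.0, 10.0 * (s_match / s_total) * (s_match / n_cls))


def add_expert_rule(
    rulebase: RuleBase,
    rule: FuzzyRule,
    train: BinDataset | None = None,
) -> RuleBase:
    """Append a hand-written rule; dominance is recomputed on ``train``
    when provided.  A duplicate rule warns and leaves the base unchanged."""
    if any(r.signature() == rule.signature() for r in rulebase.rules):
        warnings.warn(f"duplicate rule not inserted: {rule.text()}")
        return rulebase
    if len(rulebase.rules) + 1 > MAX_RULES:
        raise ValueError(f"cannot exceed {MAX_RULES} rules")
    for mark, _ in rule.antecedents:
        if mark not in rulebase.partitions:
            raise ValueError(f"rule references unknown mark {mark!r}")
    dominance = rule.dominance
    if train is not None:
        dominance = compute_dominance(rule, rulebase, train)
    new_rule = FuzzyRule(rule.antecedents, rule.consequent, dominance)
    return RuleBase(
        list(rulebase.rules) + [new_rule],
        dict(rulebase.partitions),
        rulebase.default_class,
        rulebase.default_probability,
    )
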