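"""Interval type-2 fuzzy variables, rule bases, and Mamdani-style inference.

Each signal mark is described by a three-set linguistic partition
(``low`` / ``medium`` / ``high``) of trapezoidal interval type-2 fuzzy
sets on the normalized signal range [0, 1].  A rule base is a small
collection (at most :data:`MAX_RULES`) of IF/THEN rules whose
antecedents are (mark, label) pairs and whose consequent is either
``enhancer`` or ``non_enhancer``.  Inference combines rule firing
strengths (min t-norm), aggregates them per class weighted by rule
dominance, type-reduces each interval to its midpoint, and reports the
enhancer probability as the enhancer share of the two class aggregates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

ENHANCER = "enhancer"
NON_ENHANCER = "non_enhancer"
CLASSES = (ENHANCER, NON_ENHANCER)

LABELS = ("low", "medium", "high")

#: hard explainability constraints on a rule base
MAX_RULES = 50
MAX_ANTECEDENTS = 3

DEFAULT_PROBABILITY = 0.5


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trapezoid:
    """Piecewise-linear trapezoidal membership function with breakpoints
    ``a <= b <= c <= d`` (support [a, d], plateau [b, c])."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"trapezoid breakpoints must be ordered, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        if self.b > self.a:
            m = (x > self.a) & (x < self.b)
            y[m] = (x[m] - self.a) / (self.b - self.a)
        m = (x >= self.b) & (x <= self.c)
        y[m] = 1.0
        if self.d > self.c:
            m = (x > self.c) & (x < self.d)
            y[m] = (self.d - x[m]) / (self.d - self.c)
        if y.ndim == 0:
            return float(y)
        return y

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class FuzzySet:
    """Interval type-2 fuzzy set: a linguistic label with lower and upper
    trapezoidal membership functions (``upper(x) >= lower(x)``)."""

    label: str
    lower: Trapezoid
    upper: Trapezoid

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown linguistic label {self.label!r}")
        # containment of supports/cores guarantees upper >= lower pointwise
        lo, up = self.lower, self.upper
        if not (up.a <= lo.a and up.b <= lo.b and lo.c <= up.c and lo.d <= up.d):
            raise ValueError(
                f"lower membership of {self.label!r} not contained in upper"
            )

    def membership(self, x):
        """Return ``(lower, upper)`` membership of ``x`` (scalar or array)."""
        x = _clip_to_unit(x)
        return self.lower(x), self.upper(x)

    @property
    def center(self) -> float:
        up = self.upper
        return 0.5 * (up.b + up.c)


def _clip_to_unit(x):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        warnings.warn("membership input outside [0, 1]; clipping", stacklevel=3)
        arr = np.clip(arr, 0.0, 1.0)
        if np.ndim(x) == 0:
            return float(arr)
        return arr
    return x


def make_type2_set(
    label: str, a: float, b: float, c: float, d: float, fou: float = 0.05
) -> FuzzySet:
    """Build an interval type-2 set from a type-1 trapezoid plus a symmetric
    footprint-of-uncertainty ``fou`` widening the upper and narrowing the
    lower membership on the ramps.  ``fou=0`` degenerates to type-1."""
    if fou < 0:
        raise ValueError("fou must be non-negative")
    upper = Trapezoid(max(0.0, a - fou), b, c, min(1.0, d + fou))
    lower = Trapezoid(min(a + fou, b), b, c, max(d - fou, c))
    return FuzzySet(label, lower, upper)


@dataclass(frozen=True)
class FuzzyPartition:
    """A full linguistic partition (low/medium/high) for one mark."""

    mark: str
    sets: Mapping[str, FuzzySet]

    def __post_init__(self) -> None:
        if set(self.sets) != set(LABELS):
            raise ValueError(
                f"partition for {self.mark!r} must define exactly {LABELS}"
            )
        centers = [self.sets[lab].center for lab in LABELS]
        if not (centers[0] < centers[1] < centers[2]):
            raise ValueError(
                f"partition for {self.mark!r}: set centers must be ordered "
                f"low < medium < high, got {centers}"
            )

    def membership(self, label: str, x):
        return self.sets[label].membership(x)

    def best_label(self, x: float) -> str:
        """Linguistic label with the largest midpoint membership at ``x``."""
        best, best_mu = LABELS[0], -1.0
        for lab in LABELS:
            lo, up = self.sets[lab].membership(float(x))
            mu = 0.5 * (lo + up)
            if mu > best_mu:
                best, best_mu = lab, mu
        return best

    def coverage_ok(self, n_grid: int = 501) -> bool:
        """True if every grid point of [0,1] has positive upper membership
        in at least one set."""
        x = np.linspace(0.0, 1.0, n_grid)
        total = np.zeros(n_grid)
        for lab in LABELS:
            total = np.maximum(total, self.sets[lab].upper(x))
        return bool(np.all(total > 0))

    def fingerprint(self) -> tuple:
        return tuple(
            self.sets[lab].lower.as_tuple() + self.sets[lab].upper.as_tuple()
            for lab in LABELS
        )


def partition_from_centers(
    mark: str,
    centers: Sequence[float],
    overlap: float = 0.25,
    fou: float = 0.05,
) -> FuzzyPartition:
    """Build a three-set partition anchored at ``centers = (c_low, c_med,
    c_high)``.  Adjacent supports extend ``overlap`` of the way past the
    midpoint boundary between neighbouring centers; ``overlap=0`` makes
    supports touch without intersecting."""
    c1, c2, c3 = (float(c) for c in centers)
    if not (0.0 <= c1 < c2 < c3 <= 1.0):
        raise ValueError(f"centers must be ordered inside [0,1], got {centers}")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    m1 = 0.5 * (c1 + c2)
    m2 = 0.5 * (c2 + c3)
    low = make_type2_set(
        "low", 0.0, 0.0, c1, min(1.0, m1 + overlap * (c2 - m1)), fou
    )
    med_b = c2 - 0.2 * (c2 - m1)
    med_c = c2 + 0.2 * (m2 - c2)
    med = make_type2_set(
        "medium",
        max(0.0, m1 - overlap * (m1 - c1)),
        med_b,
        med_c,
        min(1.0, m2 + overlap * (c3 - m2)),
        fou,
    )
    high = make_type2_set(
        "high", max(0.0, m2 - overlap * (m2 - c2)), c3, 1.0, 1.0, fou
    )
    return FuzzyPartition(mark, {"low": low, "medium": med, "high": high})


def default_partition(mark: str, overlap: float = 0.25, fou: float = 0.05) -> FuzzyPartition:
    return partition_from_centers(mark, (0.25, 0.5, 0.75), overlap=overlap, fou=fou)


def strong_interval(fset: FuzzySet, level: float = 0.8) -> tuple[float, float]:
    """The x-interval on which the *lower* membership is >= ``level``."""
    t = fset.lower
    lo = t.a + level * (t.b - t.a) if t.b > t.a else t.a
    hi = t.d - level * (t.d - t.c) if t.d > t.c else t.d
    if hi < lo:
        raise ValueError(f"set {fset.label!r} has empty strong region at {level}")
    return lo, hi


def weak_interval(fset: FuzzySet, level: float = 0.2) -> tuple[float, float]:
    """An x-interval on which the *upper* membership is <= ``level``
    (the larger of the two sides outside the support is returned)."""
    t = fset.upper
    left_hi = t.a + level * (t.b - t.a) if t.b > t.a else t.a
    right_lo = t.d - level * (t.d - t.c) if t.d > t.c else t.d
    left = (0.0, left_hi)
    right = (right_lo, 1.0)
    if left[1] - left[0] >= right[1] - right[0]:
        side = left
    else:
        side = right
    if side[1] <= side[0]:
        raise ValueError(f"set {fset.label!r} has no weak region at {level}")
    return side


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyRule:
    """IF <mark is label> [AND ...] THEN <class>, with at most
    :data:`MAX_ANTECEDENTS` antecedents over distinct marks."""

    antecedents: tuple[tuple[str, str], ...]
    consequent: str
    dominance: float = 1.0

    def __post_init__(self) -> None:
        ants = tuple(self.antecedents)
        object.__setattr__(self, "antecedents", ants)
        if not 1 <= len(ants) <= MAX_ANTECEDENTS:
            raise ValueError(
                f"rules carry 1..{MAX_ANTECEDENTS} antecedents, got {len(ants)}"
            )
        marks = [m for m, _ in ants]
        if len(set(marks)) != len(marks):
            raise ValueError(f"duplicate mark in rule antecedents: {marks}")
        for _, lab in ants:
            if lab not in LABELS:
                raise ValueError(f"unknown linguistic label {lab!r}")
        if self.consequent not in CLASSES:
            raise ValueError(f"unknown consequent {self.consequent!r}")
        if self.dominance < 0:
            raise ValueError("dominance must be non-negative")

    def text(self) -> str:
        cond = " AND ".join(f"{mark} is {lab}" for mark, lab in self.antecedents)
        return f"IF {cond} THEN {self.consequent}"

    def signature(self) -> tuple:
        return (tuple(sorted(self.antecedents)), self.consequent)


def parse_rule(spec: str, dominance: float = 1.0) -> FuzzyRule:
    """Parse ``"H3K4me1=high & H3K27ac=high => enhancer"`` into a rule."""
    if "=>" not in spec:
        raise ValueError(f"rule {spec!r} lacks '=>'")
    lhs, rhs = spec.split("=>", 1)
    consequent = rhs.strip().replace("-", "_")
    ants = []
    for lit in lhs.split("&"):
        lit = lit.strip()
        if "=" not in lit:
            raise ValueError(f"antecedent {lit!r} is not of the form mark=label")
        mark, lab = (p.strip() for p in lit.split("=", 1))
        ants.append((mark, lab))
    return FuzzyRule(tuple(ants), consequent, dominance)


@dataclass
class RuleBase:
    """A bounded rule list plus the linguistic partitions it refers to."""

    rules: list[FuzzyRule]
    partitions: dict[str, FuzzyPartition]
    default_class: str = NON_ENHANCER
    default_probability: float = DEFAULT_PROBABILITY
    #: weight of the default probability as a smoothing prior in the class
    #: aggregate ratio; 0 gives the plain enhancer/(enhancer+non) ratio,
    #: positive values calibrate probabilities so weak unopposed firing
    #: does not saturate at 1 (set by the trainer)
    default_weight: float = 0.0

    def __post_init__(self) -> None:
        if len(self.rules) > MAX_RULES:
            raise ValueError(f"rule base exceeds {MAX_RULES} rules")
        for rule in self.rules:
            for mark, _ in rule.antecedents:
                if mark not in self.partitions:
                    raise ValueError(f"rule references unknown mark {mark!r}")

    @property
    def marks(self) -> list[str]:
        """Marks referenced by at least one rule, in first-use order."""
        seen: dict[str, None] = {}
        for rule in self.rules:
            for mark, _ in rule.antecedents:
                seen.setdefault(mark)
        return list(seen)

    def validate_trained(self) -> None:
        present = {rule.consequent for rule in self.rules}
        if set(CLASSES) - present:
            raise ValueError(
                f"trained rule base must cover both classes, missing "
                f"{sorted(set(CLASSES) - present)}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "default_class": self.default_class,
            "default_probability": self.default_probability,
            "default_weight": self.default_weight,
            "partitions": {
                mark: {
                    lab: {
                        "lower": part.sets[lab].lower.as_tuple(),
                        "upper": part.sets[lab].upper.as_tuple(),
                    }
                    for lab in LABELS
                }
                for mark, part in sorted(self.partitions.items())
            },
            "rules": [
                {
                    "antecedents": [list(a) for a in rule.antecedents],
                    "consequent": rule.consequent,
                    "dominance": rule.dominance,
                }
                for rule in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleBase":
        partitions = {}
        for mark, sets in payload["partitions"].items():
            fsets = {
                lab: FuzzySet(lab, Trapezoid(*spec["lower"]), Trapezoid(*spec["upper"]))
                for lab, spec in sets.items()
            }
            partitions[mark] = FuzzyPartition(mark, fsets)
        rules = [
            FuzzyRule(
                tuple((m, l) for m, l in r["antecedents"]),
                r["consequent"],
                r.get("dominance", 1.0),
            )
            for r in payload["rules"]
        ]
        return cls(
            rules,
            partitions,
            payload.get("default_class", NON_ENHANCER),
            payload.get("default_probability", DEFAULT_PROBABILITY),
            payload.get("default_weight", 0.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RuleBase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_text(self) -> str:
        lines = [
            f"rule {i + 1:2d} (dominance {rule.dominance:.3f}): {rule.text()}"
            for i, rule in enumerate(self.rules)
        ]
        lines.append(
            f"default: {self.default_class} "
            f"(probability {self.default_probability:g} when no rule fires)"
        )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def membership(fset: FuzzySet, x):
    """Interval membership ``[lower, upper]`` of ``x`` in ``fset``."""
    return fset.membership(x)


def rule_firing(
    rule: FuzzyRule,
    features: Mapping[str, float],
    partitions: Mapping[str, FuzzyPartition],
) -> tuple[float, float]:
    """Min t-norm conjunction of the rule's antecedent memberships,
    applied separately to lower and upper bounds."""
    lo, up = 1.0, 1.0
    for mark, lab in rule.antecedents:
        if mark not in features:
            raise KeyError(f"feature {mark!r} required by rule is missing")
        mlo, mup = partitions[mark].membership(lab, float(features[mark]))
        lo = min(lo, mlo)
        up = min(up, mup)
    return lo, up


def infer(
    rulebase: RuleBase, features: Mapping[str, float]
) -> tuple[float, list[tuple[FuzzyRule, tuple[float, float]]]]:
    """Return ``(enhancer probability, fired rules)``.

    Class aggregates are dominance-weighted sums of firing intervals,
    type-reduced to their midpoints; the probability is the enhancer
    aggregate divided by the total.  When nothing fires the configured
    default probability is returned.
    """
    if not rulebase.rules:
        raise ValueError("cannot infer with an empty rule base")
    agg = {cls: [0.0, 0.0] for cls in CLASSES}
    fired = []
    for rule in rulebase.rules:
        lo, up = rule_firing(rule, features, rulebase.partitions)
        if up > 0.0:
            fired.append((rule, (lo, up)))
        agg[rule.consequent][0] += rule.dominance * lo
        agg[rule.consequent][1] += rule.dominance * up
    mid = {cls: 0.5 * (v[0] + v[1]) for cls, v in agg.items()}
    w0 = rulebase.default_weight
    denom = mid[ENHANCER] + mid[NON_ENHANCER] + w0
    if denom == 0.0:
        prob = rulebase.default_probability
    else:
        prob = (mid[ENHANCER] + w0 * rulebase.default_probability) / denom
    order = {id(rule): i for i, rule in enumerate(rulebase.rules)}
    fired.sort(key=lambda rf: (-0.5 * (rf[1][0] + rf[1][1]), order[id(rf[0])]))
    return prob, fired


def infer_matrix(
    rulebase: RuleBase,
    X: np.ndarray,
    feature_order: Sequence[str],
) -> np.ndarray:
    """Vectorized :func:`infer` over a (n_bins, n_marks) feature matrix.

    ``feature_order`` names the columns of ``X``; extra columns are
    ignored, missing rule-referenced marks raise ``KeyError``.
    """
    if not rulebase.rules:
        raise ValueError("cannot infer with an empty rule base")
    X = np.asarray(X, dtype=float)
    col = {mark: i for i, mark in enumerate(feature_order)}
    missing = [m for m in rulebase.marks if m not in col]
    if missing:
        raise KeyError(f"dataset lacks marks required by rules: {missing}")
    n = X.shape[0]
    memb: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def get_membership(mark: str, lab: str):
        key = (mark, lab)
        if key not in memb:
            fset = rulebase.partitions[mark].sets[lab]
            x = np.clip(X[:, col[mark]], 0.0, 1.0)
            memb[key] = (fset.lower(x), fset.upper(x))
        return memb[key]

    agg_lo = {cls: np.zeros(n) for cls in CLASSES}
    agg_up = {cls: np.zeros(n) for cls in CLASSES}
    for rule in rulebase.rules:
        f_lo = f_up = None
        for mark, lab in rule.antecedents:
            mlo, mup = get_membership(mark, lab)
            f_lo = mlo if f_lo is None else np.minimum(f_lo, mlo)
            f_up = mup if f_up is None else np.minimum(f_up, mup)
        agg_lo[rule.consequent] += rule.dominance * f_lo
        agg_up[rule.consequent] += rule.dominance * f_up
    mid_e = 0.5 * (agg_lo[ENHANCER] + agg_up[ENHANCER])
    mid_n = 0.5 * (agg_lo[NON_ENHANCER] + agg_up[NON_ENHANCER])
    w0 = rulebase.default_weight
    denom = mid_e + mid_n + w0
    probs = np.full(n, rulebase.default_probability)
    nz = denom > 0
    probs[nz] = (mid_e[nz] + w0 * rulebase.default_probability) / denom[nz]
    return probs


def explain(rulebase: RuleBase, features: Mapping[str, float]) -> str:
    """Render fired rules as natural-language IF/THEN lines, strongest first."""
    prob, fired = infer(rulebase, features)
    lines = []
    for rule, (lo, up) in fired:
        strength = 0.5 * (lo + up)
        lines.append(f"{rule.text()}  [firing {strength:.3f}]")
    if not fired:
        lines.append(
            f"no rule fired; default class {rulebase.default_class} "
            f"(probability {rulebase.default_probability:g})"
        )
    lines.append(f"enhancer probability: {prob:.3f}")
    return "\n".join(lines) + "\n"
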