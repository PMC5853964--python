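"""Expected and observed genotype-class proportions in selfing crosses.

For an F2 from a selfed F1 that is heterozygous for a deletion at each of
``n`` unlinked loci, a gamete carries the deletion allele at a locus with
transmission probability p (0.5 under Mendelian transmission), so a plant is
homozygous for the deletion at that locus with probability p^2 and loci
multiply.  With dominant markers only homozygous-deletion states are
identifiable, so classes are defined over per-locus homozygous-deletion
status; "not homozygous-deleted" aggregates heterozygotes and wild type.

A deficit of homozygous deletion classes relative to these expectations
indicates selection against transmission of the deletion-bearing chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class CrossDesign:
    """An F2 selfing design over ``n_loci`` unlinked deletion loci."""

    n_loci: int = 2
    transmission_prob_per_gamete: Sequence[float] | None = None
    generation: str = "F2"

    def __post_init__(self) -> None:
        if self.transmission_prob_per_gamete is None:
            self.transmission_prob_per_gamete = [0.5] * self.n_loci
        if len(self.transmission_prob_per_gamete) != self.n_loci:
            raise ValueError("one transmission probability per locus required")
        for p in self.transmission_prob_per_gamete:
            if not 0 <= p <= 1:
                raise ValueError(f"transmission probability {p} outside [0, 1]")


@dataclass
class GenotypeCounts:
    """Observed counts per genotype class; counts must sum to the total screened."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError(
                f"class counts sum to {sum(self.counts.values())}, not total {self.total}"
            )


def class_label(homozygous: tuple[bool, ...]) -> str:
    """Canonical label for a per-locus homozygous-deletion pattern."""
    if all(homozygous):
        return "all_homozygous_deleted"
    if not any(homozygous):
        return "none_homozygous_deleted"
    loci = [f"locus{i + 1}" for i, h in enumerate(homozygous) if h]
    return "_and_".join(loci) + "_homozygous_deleted"


def expected_genotype_proportions(design: CrossDesign) -> dict[str, float]:
    """Probability of every homozygous-deletion pattern across the loci.

    P(homozygous deletion at locus i) = p_i^2; independent loci multiply;
    the returned probabilities partition the F2 and sum to 1.  For two loci
    with p = 0.5 the double homozygote is (1/4)^2 = 1/16.
    """
    q = [p * p for p in design.transmission_prob_per_gamete]
    out: dict[str, float] = {}
    for pattern in product((True, False), repeat=design.n_loci):
        prob = 1.0
        for qi, hom in zip(q, pattern):
            prob *= qi if hom else 1 - qi
        out[class_label(pattern)] = prob
    return out


@dataclass
class Proportion:
    count: int
    total: int
    percent: float
    percent_rounded: float
    fraction: Fraction

    def __str__(self) -> str:  # e.g. "0.2% (1/457)"
        return f"{self.percent_rounded:.1f}% ({self.count}/{self.total})"


def observed_proportion(counts: GenotypeCounts, cls: str) -> Proportion:
    """Observed class proportion as a percentage (one decimal place) with the
    exact fraction alongside."""
    if counts.total <= 0:
        raise ValueError("total screened must be > 0")
    k = counts.counts.get(cls, 0)
    pct = 100.0 * k / counts.total
    return Proportion(
        count=k,
        total=counts.total,
        percent=pct,
        percent_rounded=round(pct, 1),
        fraction=Fraction(k, counts.total),
    )


@dataclass
class BiasTestResult:
    statistic: float
    df: int
    p_value: float
    p_value_method: str  # "chi_square" or "exact_binomial"
    focal_class: str
    binomial_tail: float  # exact one-sided tail for the focal class
    binomial_direction: str  # "under" or "over"


def transmission_bias_test(
    counts: GenotypeCounts,
    expected: Mapping[str, float],
    focal_class: str | None = None,
) -> BiasTestResult:
    """Goodness-of-fit test of observed genotype classes against expectation.

    The statistic is the chi-square sum((obs - exp)^2 / exp) with
    df = classes - 1.  The p-value comes from the chi-square distribution,
    except that the exact binomial tail replaces it when any expected count
    is below 5.  An exact one-sided binomial tail for the focal class
    (default: the class with the smallest expectation, typically the
    multi-homozygote class) is always reported as well, since a single
    strongly depleted class is the question of interest even when the
    chi-square approximation is formally adequate.
    """
    probs = np.array([expected[c] for c in expected], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError(f"expected probabilities sum to {probs.sum()}, not 1")
    if counts.total <= 0:
        raise ValueError("total screened must be > 0")
    classes = list(expected)
    obs = np.array([counts.counts.get(c, 0) for c in classes], dtype=float)
    exp = probs * counts.total
    for c, e, o in zip(classes, exp, obs):
        if e == 0 and o > 0:
            raise ValueError(f"class {c!r} has observations but zero expectation")

    nonzero = exp > 0
    statistic = float(((obs[nonzero] - exp[nonzero]) ** 2 / exp[nonzero]).sum())
    df = int(nonzero.sum()) - 1

    if focal_class is None:
        focal_class = classes[int(np.argmin(np.where(nonzero, exp, np.inf)))]
    k = counts.counts.get(focal_class, 0)
    p0 = expected[focal_class]
    direction = "under" if k < p0 * counts.total else "over"
    alternative = "less" if direction == "under" else "greater"
    tail = float(
        stats.binomtest(k, counts.total, p0, alternative=alternative).pvalue
    )

    if (exp[nonzero] < 5).any():
        p_value, method = tail, "exact_binomial"
    else:
        p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
        method = "chi_square"
    return BiasTestResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        p_value_method=method,
        focal_class=focal_class,
        binomial_tail=tail,
        binomial_direction=direction,
    )


def simulate_f2_counts(
    design: CrossDesign, n_plants: int, seed: int
) -> GenotypeCounts:
    """Monte-Carlo F2: each plant draws two gametes per locus independently."""
    rng = np.random.default_rng(seed)
    patterns: dict[str, int] = {
        class_label(p): 0 for p in product((True, False), repeat=design.n_loci)
    }
    per_locus = []
    for p in design.transmission_prob_per_gamete:
        g1 = rng.random(n_plants) < p
        g2 = rng.random(n_plants) < p
        per_locus.append(g1 & g2)
    per_locus = np.column_stack(per_locus)
    for row in per_locus:
        patterns[class_label(tuple(bool(x) for x in row))] += 1
    return GenotypeCounts(counts=patterns, total=n_plants)
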