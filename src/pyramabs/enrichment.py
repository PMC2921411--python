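"""Annotation-based assessment of modules and of module relationships.

Modules are scored against a user-supplied node → category table with the
upper-tail hypergeometric test (the exact closed form of the random-label
null). Two derived analyses probe whether the pyramid's link weights carry
meaning:

* p-DecreaseRatio — (min(pv_a, pv_b) − pv_ab) / min(pv_a, pv_b): positive
  exactly when merging modules a and b yields a more significant best
  enrichment than either module alone.
* proximity sign test — across all pairs of supernode links at one level,
  the link with greater proximity should show the greater p-DecreaseRatio;
  successes are tallied against a fair coin with a one-sided exact binomial
  test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from scipy.stats import binomtest, hypergeom

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "SignTestReport",
    "hypergeometric_pvalue",
    "module_enrichment",
    "p_decrease_ratio",
    "proximity_signtest",
]


@dataclass
class AnnotationTable:
    """node → categories mapping with an explicit background universe."""

    membership: dict[str, set[str]]
    background: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        if not self.background:
            self.background = frozenset(self.membership)
        missing = set(self.membership) - set(self.background)
        if missing:
            raise ValueError(
                f"{len(missing)} annotated node(s) missing from the background"
            )

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for node, cats in self.membership.items():
            if node in self.background:
                for c in cats:
                    sizes[c] = sizes.get(c, 0) + 1
        return sizes


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    N: background size, K: category size, n: module (annotated) size,
    k: overlap. Computed through the survival function, which is stable for
    the small tail probabilities enrichment analyses produce.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    best_category: str | None
    best_pvalue: float | None
    per_category: dict[str, float]
    n_annotated: int

    @property
    def no_annotation(self) -> bool:
        return self.best_category is None


def module_enrichment(
    module: frozenset[str] | set[str],
    annotations: AnnotationTable,
    bonferroni: bool = False,
) -> EnrichmentResult:
    """Best (smallest) raw hypergeometric p over the module's categories.

    Only categories with at least one member inside the module are tested;
    ``bonferroni=True`` multiplies each p by the number tested (capped at 1).
    Raw minimum p is the default report. A module with no annotated nodes
    yields a defined no-annotation result.
    """
    background = annotations.background
    annotated = frozenset(module) & background
    if not annotated:
        return EnrichmentResult(None, None, {}, 0)
    N = len(background)
    n = len(annotated)
    sizes = annotations.category_sizes()
    overlaps: dict[str, int] = {}
    for node in annotated:
        for cat in annotations.membership.get(node, ()):
            overlaps[cat] = overlaps.get(cat, 0) + 1
    per = {
        cat: hypergeometric_pvalue(k, n, sizes[cat], N) for cat, k in overlaps.items()
    }
    if bonferroni:
        m = len(per)
        per = {cat: min(1.0, p * m) for cat, p in per.items()}
    best_cat = min(per, key=lambda c: (per[c], c))
    return EnrichmentResult(best_cat, per[best_cat], per, n)


def p_decrease_ratio(pv_a: float, pv_b: float, pv_ab: float) -> float:
    """(min(pv_a, pv_b) − pv_ab) / min(pv_a, pv_b); positive iff the merged
    module beats both parents."""
    for v in (pv_a, pv_b, pv_ab):
        if not 0 < v <= 1:
            raise ValueError(f"p-values must lie in (0, 1], got {v}")
    m = min(pv_a, pv_b)
    return (m - pv_ab) / m


@dataclass
class SignTestReport:
    successes: int
    trials: int
    pvalue: float | None
    significant: bool
    alpha: float
    n_links_tested: int
    insufficient_data: bool = False


def proximity_signtest(
    level,
    annotations: AnnotationTable,
    alpha: float = 0.01,
    max_pairs: int | None = None,
) -> SignTestReport:
    """Do stronger supernode links predict larger enrichment gains on merge?

    For every ordered pair of abstract-network links ((a,b), (c,d)) with
    strictly greater proximity on (a,b), a success is counted when the
    p-DecreaseRatio of merging a with b exceeds that of merging c with d;
    ties contribute no trial (standard sign-test handling). The report holds
    the one-sided exact binomial p against success probability 1/2. Links
    touching unannotated modules are skipped; fewer than two comparable
    links yields a defined insufficient-data result.
    """
    modules = level.module_set.as_dict()
    abstract = level.abstract_network
    # unordered links with total (direction-summed) proximity
    seen: dict[tuple[str, str], float] = {}
    for u, v, w in abstract.links():
        key = (u, v) if u <= v else (v, u)
        if abstract.directed:
            seen[key] = seen.get(key, 0.0) + w
        else:
            seen[key] = w
    best: dict[str, float | None] = {}
    for mid, members in modules.items():
        res = module_enrichment(members, annotations)
        best[mid] = res.best_pvalue
    ratios: list[tuple[float, float]] = []  # (proximity, p-DecreaseRatio)
    for (a, b), prox in sorted(seen.items()):
        if best.get(a) is None or best.get(b) is None:
            continue
        merged = module_enrichment(modules[a] | modules[b], annotations)
        if merged.best_pvalue is None:
            continue
        ratios.append((prox, p_decrease_ratio(best[a], best[b], merged.best_pvalue)))
    if len(ratios) < 2 or len({p for p, _ in ratios}) < 2:
        return SignTestReport(0, 0, None, False, alpha, len(ratios), True)
    successes = trials = 0
    n_compared = 0
    for (p1, r1), (p2, r2) in combinations(ratios, 2):
        if p1 == p2:
            continue
        if max_pairs is not None and n_compared >= max_pairs:
            break
        n_compared += 1
        hi_ratio, lo_ratio = (r1, r2) if p1 > p2 else (r2, r1)
        if hi_ratio == lo_ratio:
            continue  # tie: no trial
        trials += 1
        successes += hi_ratio > lo_ratio
    if trials == 0:
        return SignTestReport(0, 0, None, False, alpha, len(ratios), True)
    pvalue = float(binomtest(successes, trials, 0.5, alternative="greater").pvalue)
    return SignTestReport(
        successes, trials, pvalue, pvalue <= alpha, alpha, len(ratios), False
    )
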