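"""Per-site causal networks, standardized link strengths and loop weights.

All ordered pairs among a site's variables are quantified by the per-link
protocol; linkage strengths are then standardized within the site
(SLS = LS / max LS, so the strongest link scores 1) to make sites with
different overall cross-map skill comparable.  Feedback loops are scored by
their loop weight — the geometric mean of the member links' SLS (after
Neutel) — for the pairwise cycles X -> Y -> X and the four triangular cycles
among richness, biomass and a nutrient:

* Type I (diversity effects first):  richness -> biomass -> nutrient -> richness
* Type II (biomass effects first):   biomass -> richness -> nutrient -> biomass

each with nitrate (suffix -N) or phosphate (-P).  An exogenous variable
(temperature) can force the system but cannot be fed back on, so links into
it are quantified only as false-positive diagnostics and never enter loops.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .pipeline import CCMConfig, CCMResult, quantify_link
from .preprocessing import ProcessedSeries
from .synthetic import GroundTruthNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CausalLink",
    "SiteNetwork",
    "FeedbackLoop",
    "build_site_network",
    "standardize_network",
    "pairwise_loop",
    "triangular_loops",
    "all_pairwise_loops",
    "directional_bias",
    "recovery_metrics",
]

LOOP_TYPES = ("pairwise", "I-N", "I-P", "II-N", "II-P")


@dataclass
class CausalLink:
    """One directed link with raw and standardized strength."""

    cause: str
    effect: str
    LS: float
    significant: bool
    SLS: float | None = None
    se: float | None = None
    result: CCMResult | None = None


@dataclass
class SiteNetwork:
    """All quantified directed links among one site's variables."""

    site: str
    variables: tuple[str, ...]
    links: dict[tuple[str, str], CausalLink]
    exogenous: frozenset[str] = frozenset()
    standardized: bool = False

    def link(self, cause: str, effect: str) -> CausalLink:
        try:
            return self.links[(cause, effect)]
        except KeyError:
            raise ValidationError(f"no link record for {cause} -> {effect}") from None

    def significant_links(self) -> list[CausalLink]:
        return [l for l in self.links.values() if l.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": self.site,
                "cause": l.cause,
                "effect": l.effect,
                "LS": l.LS,
                "SLS": l.SLS,
                "significant": l.significant,
                "se": l.se,
            }
            for l in self.links.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class FeedbackLoop:
    """An ordered cycle of links with its geometric-mean loop weight."""

    loop_type: str
    links: tuple[CausalLink, ...]
    loop_weight: float
    significant: bool

    @property
    def path(self) -> str:
        names = [l.cause for l in self.links] + [self.links[-1].effect]
        return " -> ".join(names)


def build_site_network(
    dataset: dict[str, ProcessedSeries],
    variables: list[str] | None = None,
    config: CCMConfig = CCMConfig(),
    exogenous: set[str] | frozenset[str] = frozenset(),
    site: str = "site",
) -> SiteNetwork:
    """Quantify every ordered pair of variables at one site.

    Links into exogenous variables are computed like any other (they serve as
    false-positive diagnostics) but are excluded from loops and recovery
    scoring downstream.  Per-link seeds are derived deterministically from
    the config seed and the link's names, so the network is reproducible
    regardless of evaluation order.
    """
    if variables is None:
        variables = sorted(dataset.keys())
    if len(variables) < 2:
        raise ValidationError("need at least 2 variables")
    missing = [v for v in variables if v not in dataset]
    if missing:
        raise ValidationError(f"variables absent from dataset: {missing}")
    links: dict[tuple[str, str], CausalLink] = {}
    for cause, effect in itertools.permutations(variables, 2):
        seed = _link_seed(config.seed, site, cause, effect)
        res = quantify_link(
            dataset[cause], dataset[effect], config,
            cause_name=cause, effect_name=effect, seed=seed,
        )
        links[(cause, effect)] = CausalLink(
            cause=cause,
            effect=effect,
            LS=res.LS,
            significant=res.significant,
            se=res.se,
            result=res,
        )
    return SiteNetwork(
        site=site,
        variables=tuple(variables),
        links=links,
        exogenous=frozenset(exogenous),
    )


def _link_seed(master: int, site: str, cause: str, effect: str) -> int:
    import zlib

    h = zlib.crc32(f"{site}|{cause}|{effect}".encode())
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, h]).generate_state(1)[0] % (2**31))


def standardize_network(net: SiteNetwork, significant_only: bool = False) -> SiteNetwork:
    """Set SLS = LS / max(LS) on every link, within this site only.

    The maximum runs over all directed links among the site's variables,
    significant or not, by default; ``significant_only`` restricts the
    denominator to significant links.  Idempotent; raises if every eligible
    LS is zero.
    """
    pool = [l for l in net.links.values() if l.significant or not significant_only]
    if not pool:
        raise ValidationError("cannot standardize: no eligible links")
    ls_max = max(l.LS for l in pool)
    if ls_max <= 0:
        raise ValidationError("cannot standardize: all linkage strengths are zero")
    links = {
        key: replace(l, SLS=l.LS / ls_max) for key, l in net.links.items()
    }
    return SiteNetwork(
        site=net.site,
        variables=net.variables,
        links=links,
        exogenous=net.exogenous,
        standardized=True,
    )


def _require_standardized(net: SiteNetwork) -> None:
    if not net.standardized:
        raise ValidationError("network must be standardized first")


def _geometric_mean(values: list[float]) -> float:
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValidationError("loop weight undefined for negative SLS")
    return float(np.prod(v) ** (1.0 / len(v)))


def pairwise_loop(net: SiteNetwork, var_a: str, var_b: str) -> FeedbackLoop:
    """Two-link feedback A -> B -> A; weight = sqrt(SLS_ab * SLS_ba)."""
    _require_standardized(net)
    ab = net.link(var_a, var_b)
    ba = net.link(var_b, var_a)
    return FeedbackLoop(
        loop_type="pairwise",
        links=(ab, ba),
        loop_weight=_geometric_mean([ab.SLS, ba.SLS]),
        significant=ab.significant and ba.significant,
    )


def all_pairwise_loops(net: SiteNetwork) -> dict[tuple[str, str], FeedbackLoop]:
    """Pairwise loops for every unordered endogenous pair."""
    endo = [v for v in net.variables if v not in net.exogenous]
    return {
        (a, b): pairwise_loop(net, a, b)
        for a, b in itertools.combinations(endo, 2)
    }


#: triangular cycles as ordered (cause, effect) link chains
_TRIANGLES = {
    "I-N": (("richness", "biomass"), ("biomass", "no3"), ("no3", "richness")),
    "I-P": (("richness", "biomass"), ("biomass", "po4"), ("po4", "richness")),
    "II-N": (("biomass", "richness"), ("richness", "no3"), ("no3", "biomass")),
    "II-P": (("biomass", "richness"), ("richness", "po4"), ("po4", "biomass")),
}


def triangular_loops(net: SiteNetwork) -> dict[str, FeedbackLoop]:
    """The four diversity-biomass-nutrient triangles (I-N, I-P, II-N, II-P)."""
    _require_standardized(net)
    needed = {"richness", "biomass", "no3", "po4"}
    absent = needed - set(net.variables)
    if absent:
        raise ValidationError(f"missing variables for triangular loops: {sorted(absent)}")
    loops = {}
    for name, chain in _TRIANGLES.items():
        links = tuple(net.link(c, e) for c, e in chain)
        loops[name] = FeedbackLoop(
            loop_type=name,
            links=links,
            loop_weight=_geometric_mean([l.SLS for l in links]),
            significant=all(l.significant for l in links),
        )
    return loops


def directional_bias(net: SiteNetwork, var_a: str, var_b: str) -> float:
    """SLS(A -> B) - SLS(B -> A); positive when A's effect dominates."""
    _require_standardized(net)
    return float(net.link(var_a, var_b).SLS - net.link(var_b, var_a).SLS)


def recovery_metrics(
    net: SiteNetwork, truth: GroundTruthNetwork
) -> tuple[float, float]:
    """Precision and recall of significant links against a known edge set.

    Self-links and links into exogenous variables are excluded from both the
    predicted and the true edge sets.  With no predicted edges precision is 1
    by convention (no false positives were asserted); with an empty truth
    recall is 1.
    """
    def admissible(cause: str, effect: str) -> bool:
        return cause != effect and effect not in net.exogenous

    predicted = {
        (l.cause, l.effect)
        for l in net.significant_links()
        if admissible(l.cause, l.effect)
    }
    true_edges = {e for e in truth.edges if admissible(*e)}
    tp = len(predicted & true_edges)
    if predicted:
        precision = tp / len(predicted)
    else:
        precision = 1.0
        logger.info("recovery_metrics: no significant links; precision = 1 by convention")
    recall = tp / len(true_edges) if true_edges else 1.0
    return float(precision), float(recall)


def loops_frame(net: SiteNetwork) -> pd.DataFrame:
    """Long table of every pairwise and triangular loop at one site."""
    rows = []
    for (a, b), loop in all_pairwise_loops(net).items():
        rows.append(
            {
                "site": net.site,
                "loop_type": "pairwise",
                "members": f"{a}<->{b}",
                "loop_weight": loop.loop_weight,
                "significant": loop.significant,
            }
        )
    try:
        tris = triangular_loops(net)
    except ValidationError:
        tris = {}
    for name, loop in tris.items():
        rows.append(
            {
                "site": net.site,
                "loop_type": name,
                "members": loop.path,
                "loop_weight": loop.loop_weight,
                "significant": loop.significant,
            }
        )
    return pd.DataFrame(rows)
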