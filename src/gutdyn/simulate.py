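"""Synthetic longitudinal infant-gut cohorts with planted structure.

The generator emulates the statistical features the downstream analyses
assume: ~12 infants sampled near-daily over the first year with irregular
gaps, log-normal library sizes, four dominant phyla with individual-specific
smooth trajectories, a planted *Bifidobacterium*-like bloom on one
Actinobacteria OTU that drives a period of compositional convergence, one
late-starting infant (first sample at day 54) to exercise the exclusion
rule, and one twin pair sharing a latent draw up to small coupling noise.

Latent model, per infant i, OTU o, day t (1..365), with tau = (t-183)/182:

    logit(i, o, t) = base(o) + shared_slope(o) * tau
                     + g(t) * [static(i, o) + wiggle(i, o, t)]
                     + bloom(o) * exp(-(t - c)^2 / (2 w^2))

where base(o) encodes the phylum mean fractions plus a static per-OTU
effect; shared_slope is a cohort-wide developmental drift (age is the main
structuring factor within every infant, as in real cohorts); static and
wiggle are each infant's own persistent offsets and a cubic-spline smooth
through independent 30-day knot draws (autocorrelated, stationary
individuality, both of scale individuality_sd); and g(t) = (1 - r) +
r * exp(-(t-1)/120), with r = convergence_rate, shrinks the individual
components through the year -- fast at first, flattening later -- which is
what makes the cohort's contemporaneous distances decline overall without
a spurious year-end collapse. The Gaussian bloom term on the designated Actinobacteria OTU is
shared by the cohort and drives the accelerated-convergence window.
Compositions are the softmax over OTUs, so taxa outside the bloom are
depressed compensatorily inside the window.
Counts are Dirichlet-multinomial around the latent composition with
log-normal library sizes. Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from skbio import TreeNode

from .io import Cohort, validate_cohort
from .interpolate import InfantSeries

logger = logging.getLogger(__name__)

# phylum mean fractions (cohort-level dominance structure); renormalized to
# sum to exactly 1 at config construction
DEFAULT_PHYLUM_FRACTIONS = {
    "Bacteroidetes": 0.323,
    "Actinobacteria": 0.161,
    "Firmicutes": 0.354,
    "Proteobacteria": 0.155,
}

N_DAYS = 365


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale: 150 OTUs and ~1,600-read libraries (the field
    cohort's ~164,000-read libraries scaled down x100) keep the full
    pipeline fast; :meth:`paper_scale` restores full-size libraries and OTU
    richness for stress tests. ``sampling_rate`` 0.65 over ~345 candidate
    days yields ~224 samples per infant.
    """

    n_infants: int = 12
    n_otus: int = 150
    sampling_rate: float = 0.65
    first_day_range: tuple[int, int] = (1, 9)
    last_day_range: tuple[int, int] = (352, 367)
    library_size_log_mean: float = 7.352  # lognormal mean ~1,642 reads
    library_size_log_sd: float = 0.323  # matches the field cohort's CV of 0.33
    phylum_base_fractions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_FRACTIONS)
    )
    bloom_center_day: float = 95.0
    bloom_half_width: float = 35.0
    bloom_peak_boost: float = 3.5
    bloom_base_bonus: float = 2.0  # makes the bloom OTU dominate its phylum
    bloom_individual_damp: float = 0.5  # bloom OTU keeps this fraction of individual noise
    overdispersion: float = 200.0  # Dirichlet concentration
    individuality_sd: float = 1.2  # per-infant offset scale, static and knots (logits)
    shared_trend_sd: float = 1.5  # cohort-wide per-OTU drift (common maturation)
    convergence_rate: float = 0.5  # total fractional decay of individual effects
    convergence_timescale: float = 120.0  # e-folding time (days) of that decay
    otu_base_sd: float = 1.2  # static per-OTU effect scale (logits)
    knot_spacing: int = 30  # days between random-walk knots
    late_starter: tuple[str, int] | None = ("ID8", 54)
    twin_pair: tuple[str, str, float] | None = ("ID10", "ID11", 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_infants < 2:
            raise ValueError("need at least 2 infants")
        if self.n_otus < len(self.phylum_base_fractions):
            raise ValueError("need at least one OTU per phylum")
        if not (0 < self.sampling_rate <= 1):
            raise ValueError("sampling_rate must lie in (0, 1]")
        total = sum(self.phylum_base_fractions.values())
        if abs(total - 1.0) > 0.02:
            raise ValueError(f"phylum fractions sum to {total:.3f}, far from 1")
        if abs(total - 1.0) > 1e-9:
            self.phylum_base_fractions = {
                k: v / total for k, v in self.phylum_base_fractions.items()
            }
        for name in ("overdispersion", "bloom_half_width", "library_size_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.convergence_rate < 1):
            raise ValueError("convergence_rate must lie in [0, 1)")
        if not (
            1 <= self.bloom_center_day - self.bloom_half_width
            and self.bloom_center_day + self.bloom_half_width <= N_DAYS
        ):
            raise ValueError("bloom window must lie inside the day range")
        if self.twin_pair is not None:
            a, b, sd = self.twin_pair
            if a == b or sd < 0:
                raise ValueError("twin pair must name two infants with noise sd >= 0")

    @property
    def infant_ids(self) -> list[str]:
        return [f"ID{i + 1}" for i in range(self.n_infants)]

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationConfig":
        """Full-size conditions: 1736 OTUs, ~164,215-read libraries."""
        defaults = dict(
            n_otus=1736,
            library_size_log_mean=float(np.log(164215) - 0.323**2 / 2),
            library_size_log_sd=0.323,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def strong_trend(cls, **overrides) -> "SimulationConfig":
        """Directed-drift-dominated variant for temporal-structure checks."""
        defaults = dict(shared_trend_sd=2.5, individuality_sd=0.8)
        defaults.update(overrides)
        return cls(**defaults)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def allocate_phyla(n_otus: int, fractions: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of OTU counts to phyla."""
    names = list(fractions)
    raw = np.array([fractions[p] * n_otus for p in names])
    counts = np.floor(raw).astype(int)
    counts[counts == 0] = 1
    remainder_order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    i = 0
    while counts.sum() < n_otus:
        counts[remainder_order[i % len(names)]] += 1
        i += 1
    while counts.sum() > n_otus:
        j = int(np.argmax(counts))
        counts[j] -= 1
    phyla: list[str] = []
    for name, c in zip(names, counts):
        phyla.extend([name] * int(c))
    return phyla


def generate_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic ranked lineages; OTU1 is the Bifidobacterium-like bloom OTU."""
    order = ["Actinobacteria", "Bacteroidetes", "Firmicutes", "Proteobacteria"]
    fractions = {p: config.phylum_base_fractions[p] for p in order}
    phyla = allocate_phyla(config.n_otus, fractions)
    rows = []
    genus_counter: dict[str, int] = {}
    for i, ph in enumerate(phyla):
        otu = f"OTU{i + 1}"
        g_idx = genus_counter.get(ph, 0)
        genus_counter[ph] = g_idx + 1
        genus = f"{ph[:4]}_genus_{g_idx // 5 + 1}"
        if i == 0:
            genus = "Bifidobacterium"
        rows.append(
            {
                "otu_id": otu,
                "domain": "Bacteria",
                "phylum": ph,
                "class": f"{ph}_class",
                "order": f"{ph}_order",
                "family": f"{ph}_family",
                "genus": genus,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def generate_tree(n_otus: int, taxonomy: pd.DataFrame, seed: int) -> TreeNode:
    """Random rooted binary phylogeny in which phyla form clades.

    Within each phylum, leaves are joined in random order with exponential
    branch lengths (a coalescent-flavoured topology); the phylum subtrees
    are then grafted onto a backbone with longer stems, so phylum-level
    community differences are visible to UniFrac.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)
    otu_ids = list(taxonomy.index[:n_otus])
    by_phylum: dict[str, list[TreeNode]] = {}
    for otu in otu_ids:
        by_phylum.setdefault(str(taxonomy.loc[otu, "phylum"]), []).append(TreeNode(name=otu))

    def join_random(nodes: list[TreeNode], scale: float, extra: float = 0.0) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            left.length = float(rng.exponential(scale) + extra)
            right.length = float(rng.exponential(scale) + extra)
            nodes.append(TreeNode(children=[left, right]))
        return nodes[0]

    clades = [join_random(nodes, scale=0.1) for _, nodes in sorted(by_phylum.items())]
    root = clades[0] if len(clades) == 1 else join_random(clades, scale=0.3, extra=0.4)
    root.length = None
    return root


@dataclasses.dataclass
class LatentTrajectories:
    """Ground-truth per-infant compositions on the full day grid.

    ``compositions`` is (n_infants, 365, n_otus); each day's row sums to 1.
    """

    infant_ids: list[str]
    days: np.ndarray
    otu_ids: list[str]
    compositions: np.ndarray
    taxonomy: pd.DataFrame
    bloom_otu: str
    bloom_center_day: float
    bloom_half_width: float

    def composition(self, infant_id: str) -> pd.DataFrame:
        i = self.infant_ids.index(infant_id)
        return pd.DataFrame(
            self.compositions[i],
            index=pd.Index(self.days, name="day"),
            columns=self.otu_ids,
        )

    def as_series(self, infant_ids=None) -> dict[str, InfantSeries]:
        """Latent compositions repackaged as (already equal-length) series."""
        ids = list(infant_ids) if infant_ids is not None else list(self.infant_ids)
        out = {}
        for inf in ids:
            frame = self.composition(inf)
            frame.index = pd.RangeIndex(1, len(frame) + 1, name="pseudo_day")
            out[inf] = InfantSeries(
                infant_id=inf, grid_days=self.days.astype(float), values=frame
            )
        return out


def generate_latent(config: SimulationConfig) -> LatentTrajectories:
    """Draw the smooth latent trajectories for every infant (seeded stream 1)."""
    rng = _rng(config.seed, 1)
    taxonomy = generate_taxonomy(config)
    otu_ids = list(taxonomy.index)
    phyla = taxonomy["phylum"].to_numpy()
    n_otus = config.n_otus
    days = np.arange(1, N_DAYS + 1)
    fractions = config.phylum_base_fractions
    counts = pd.Series(phyla).value_counts()
    base = np.array([np.log(fractions[p] / counts[p]) for p in phyla])
    base = base + rng.normal(scale=config.otu_base_sd, size=n_otus)
    bloom_otu = otu_ids[0]
    # the bloom OTU's baseline is structural, not drawn: its dynamics are the
    # planted signal, so it is exempted from the cohort-level base lottery
    base[0] = np.log(fractions[phyla[0]] / counts[phyla[0]]) + config.bloom_base_bonus

    # knots at even spacing, extending past day 365 so the last interval is
    # regular (a short terminal interval would put fast wiggle at year end)
    knot_days = np.arange(1, N_DAYS + config.knot_spacing + 1, config.knot_spacing, dtype=float)
    n_knots = len(knot_days)

    infant_ids = config.infant_ids
    twin = config.twin_pair if config.twin_pair is not None else (None, None, 0.0)
    twin_a, twin_b, twin_sd = twin

    draws: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for inf in infant_ids:
        static = rng.normal(scale=config.individuality_sd, size=n_otus)
        knots = rng.normal(scale=config.individuality_sd, size=(n_knots, n_otus))
        draws[inf] = (static, knots)
    if twin_a in draws and twin_b in draws:
        static_a, knots_a = draws[twin_a]
        draws[twin_b] = (
            static_a + rng.normal(scale=twin_sd, size=n_otus),
            knots_a + rng.normal(scale=twin_sd, size=(n_knots, n_otus)),
        )

    bloom_term = config.bloom_peak_boost * np.exp(
        -0.5 * ((days - config.bloom_center_day) / config.bloom_half_width) ** 2
    )
    # bounded shared drift: an unclipped tail draw would let a single OTU
    # dominate every infant at the year ends, collapsing distances there
    shared_slopes = np.clip(
        rng.normal(scale=config.shared_trend_sd, size=n_otus),
        -2.0 * config.shared_trend_sd,
        2.0 * config.shared_trend_sd,
    )
    shared_slopes[0] = 0.0  # the Gaussian bloom term is the bloom OTU's shared dynamic
    tau = (days[:, None] - 183.0) / 182.0
    envelope = (1.0 - config.convergence_rate) + config.convergence_rate * np.exp(
        -(days[:, None] - 1.0) / config.convergence_timescale
    )
    # the bloom is a cohort-coherent response, so the bloom OTU carries only
    # a damped share of each infant's idiosyncratic variation
    damp = np.ones(n_otus)
    damp[0] = config.bloom_individual_damp
    compositions = np.empty((len(infant_ids), N_DAYS, n_otus))
    for i, inf in enumerate(infant_ids):
        static, knots = draws[inf]
        wiggle = CubicSpline(knot_days, knots, axis=0, bc_type="natural")(days)
        logit = base[None, :] + shared_slopes[None, :] * tau
        logit += envelope * ((static[None, :] + wiggle) * damp[None, :])
        logit[:, 0] += bloom_term
        logit -= logit.max(axis=1, keepdims=True)
        expl = np.exp(logit)
        compositions[i] = expl / expl.sum(axis=1, keepdims=True)
    return LatentTrajectories(
        infant_ids=infant_ids,
        days=days,
        otu_ids=otu_ids,
        compositions=compositions,
        taxonomy=taxonomy,
        bloom_otu=bloom_otu,
        bloom_center_day=config.bloom_center_day,
        bloom_half_width=config.bloom_half_width,
    )


def sample_counts(
    latent: LatentTrajectories, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw sampled days, library sizes and Dirichlet-multinomial counts.

    Days are included independently at ``sampling_rate`` within each
    infant's own [first, last] day range; library sizes are log-normal;
    counts are multinomial around a Dirichlet draw with concentration
    ``overdispersion * latent composition``. Seeded stream 2.
    """
    rng = _rng(config.seed, 2)
    rows = []
    meta_rows = []
    late = dict([config.late_starter]) if config.late_starter else {}
    for i, inf in enumerate(latent.infant_ids):
        if inf in late:
            first = int(late[inf])
        else:
            first = int(rng.integers(config.first_day_range[0], config.first_day_range[1] + 1))
        last = int(rng.integers(config.last_day_range[0], config.last_day_range[1] + 1))
        last = min(last, N_DAYS)
        candidates = np.arange(first, last + 1)
        sampled = None
        for attempt in range(10):
            mask = rng.random(len(candidates)) < config.sampling_rate
            if mask.any():
                sampled = candidates[mask]
                break
            logger.warning("infant %s drew zero sampled days (attempt %d)", inf, attempt + 1)
        if sampled is None:
            raise RuntimeError(f"infant {inf} produced no sampled days in 10 attempts")
        libs = np.maximum(
            1,
            np.round(
                rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, len(sampled))
            ).astype(np.int64),
        )
        comp_all = latent.compositions[i]
        for day, lib in zip(sampled, libs):
            comp = comp_all[day - 1]
            alpha = config.overdispersion * comp
            gams = rng.standard_gamma(alpha)
            total = gams.sum()
            p = comp if total <= 0 else gams / total
            counts = rng.multinomial(int(lib), p)
            sid = f"{inf}_d{day:03d}"
            rows.append(pd.Series(counts, index=latent.otu_ids, name=sid))
            meta_rows.append(
                {"sample_id": sid, "infant_id": inf, "day_since_birth": int(day), "preservation": "frozen"}
            )
    counts_df = pd.DataFrame(rows)
    counts_df.index.name = "sample_id"
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts_df, meta_df


@dataclasses.dataclass
class SimulationResult:
    cohort: Cohort
    latent: LatentTrajectories
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate a full validated cohort bundle plus its latent ground truth."""
    config = config or SimulationConfig()
    latent = generate_latent(config)
    tree = generate_tree(config.n_otus, latent.taxonomy, seed=config.seed)
    counts, meta = sample_counts(latent, config)
    cohort = validate_cohort(counts, latent.taxonomy, meta, tree)
    logger.info(
        "simulated cohort: %d infants, %d OTUs, %d samples (seed %d)",
        config.n_infants, config.n_otus, len(counts), config.seed,
    )
    return SimulationResult(cohort=cohort, latent=latent, config=config)


def truth_table(latent: LatentTrajectories) -> pd.DataFrame:
    """Ground-truth table for serialization: OTU phylum map and bloom window."""
    df = latent.taxonomy[["phylum"]].copy()
    df["is_bloom_otu"] = df.index == latent.bloom_otu
    df.attrs["bloom_center_day"] = latent.bloom_center_day
    df.attrs["bloom_half_width"] = latent.bloom_half_width
    return df


def planted_convergence_window(
    latent: LatentTrajectories,
    infant_ids=None,
    metric: str = "bray_curtis",
    df: int = 9,
    slope_fraction: float = 0.1,
) -> tuple[float, float] | None:
    """The convergence window implied by the noise-free latent compositions.

    Runs the same profile + detector machinery on the latent trajectories
    themselves (no sampling noise, no interpolation error); recovery tests
    compare windows detected from sampled counts against this planted
    window.
    """
    from .convergence import contemporaneous_distances, detect_window

    series = latent.as_series(infant_ids)
    profile = contemporaneous_distances(series, metric=metric)
    return detect_window(profile, df=df, slope_fraction=slope_fraction)
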