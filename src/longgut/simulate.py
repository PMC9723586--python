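"""Synthetic longitudinal study bundles with known ground truth.

The generator emulates the sampling design of a year-long study of five
wild lemurs — a handful of individuals sampled a few times per month over
twelve months across a dry (April-October) and a rainy (November-March)
season — together with seasonal feeding and affiliation rates (min/h),
monthly precipitation (mm), a random phylogeny over taxa, and taxon count
tables drawn from a latent Gaussian log-linear model.

The latent model mirrors the analysis model: per sample ``s`` (of
individual ``i``) and taxon ``t``,

    latent(s, t) = baseline_t + v_t + u_i + w_s
                   + sum_p (beta_p + b_{t,p} + c_{i,p} + d_{ti,p}) x_p(s)
                   + eps_{s,t},

with all random draws from centered normals with configurable SDs; sample
proportions are the softmax of the latent row and counts are multinomial at
a negative-binomial library size. Every draw is stored in a
:class:`TruthRecord` so downstream estimates can be checked against a known
truth.

A caveat that shapes the defaults: a *common* covariate effect (beta) shifts
every taxon's log-abundance equally, so it cancels exactly in the softmax
and again in the CLR transform — compositional data carry no information
about it. Identifiable ground truth lives in the taxon-specific slope
contrasts, which is why the default plants ``beta = 0`` and a nonzero
``tau`` for the fruit slope.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .core import (
    BEHAVIOR_RATE_COLUMNS,
    CountTable,
    assign_season,
    read_behavior,
    read_climate,
    read_count_table,
    read_metadata,
    read_newick,
    write_behavior,
    write_climate,
    write_count_table,
    write_metadata,
)

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "StudyBundle",
    "PREDICTORS",
    "generate_tree",
    "generate_covariates",
    "generate_counts",
    "generate_study",
    "write_bundle",
    "load_bundle",
]

#: predictor order used throughout: behavior rates (min/h) then climate (mm)
PREDICTORS = (*BEHAVIOR_RATE_COLUMNS, "precipitation_mm")


def _zero_effects() -> dict[str, float]:
    return {p: 0.0 for p in PREDICTORS}


@dataclass
class SynthConfig:
    """Study design, covariate templates, and effect scales.

    Defaults emulate the study conditions: 5 individuals, 12 months, 2
    samples per individual per month, precipitation concentrated in the
    rainy season, fruit feeding peaking in the rainy season and leaf feeding
    in the dry season. Effect defaults plant a single nonzero signal — a
    taxon-specific fruit slope (``tau["fruit_rate"]``) — against modest
    intercept heterogeneity and residual noise.
    """

    n_individuals: int = 5
    n_months: int = 12
    samples_per_month: int = 2
    n_taxa: int = 30
    year: int = 2018

    # library sizes: negative binomial around the mean with dispersion
    # (shape) parameter; larger dispersion = closer to Poisson
    depth_mean: float = 10_000.0
    depth_dispersion: float = 10.0

    # covariate seasonal templates (min/h for rates, mm for precipitation)
    precip_dry_mean: float = 10.0
    precip_rainy_mean: float = 180.0
    precip_noise: float = 20.0
    fruit_mean: float = 6.0
    fruit_amplitude: float = 4.0
    leaf_mean: float = 6.0
    leaf_amplitude: float = 4.0
    flower_mean: float = 2.0
    flower_amplitude: float = 1.5
    affiliation_mean: float = 3.0
    affiliation_amplitude: float = 1.0
    behavior_noise: float = 1.5

    # effect scales (CLR units per covariate unit, or plain SDs)
    beta: dict[str, float] = field(default_factory=_zero_effects)
    tau: dict[str, float] = field(
        default_factory=lambda: {**_zero_effects(), "fruit_rate": 0.08}
    )
    individual_slope_sd: dict[str, float] = field(default_factory=_zero_effects)
    taxon_individual_slope_sd: dict[str, float] = field(default_factory=_zero_effects)
    baseline_sd: float = 1.0
    individual_sd: float = 0.1
    taxon_sd: float = 0.25
    sample_sd: float = 0.1
    taxon_individual_sd: float = 0.15
    residual_sd: float = 0.3
    #: > 0 sharpens rainy-season compositions (lower evenness, hence lower
    #: detected richness/PD), emulating season-dependent alpha diversity
    season_evenness_effect: float = 0.0

    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        for name in ("beta", "tau", "individual_slope_sd", "taxon_individual_slope_sd"):
            d = getattr(self, name)
            missing = [p for p in PREDICTORS if p not in d]
            if missing:
                raise ValueError(f"{name} missing predictors {missing}")
        sds = [
            *(self.tau[p] for p in PREDICTORS),
            *(self.individual_slope_sd[p] for p in PREDICTORS),
            *(self.taxon_individual_slope_sd[p] for p in PREDICTORS),
            self.baseline_sd,
            self.individual_sd,
            self.taxon_sd,
            self.sample_sd,
            self.taxon_individual_sd,
            self.residual_sd,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                value = d[f.name]
                if isinstance(getattr(base, f.name), dict) and isinstance(value, dict):
                    value = {**getattr(base, f.name), **value}
                merged[f.name] = value
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TruthRecord:
    """Every random draw behind a synthetic count table."""

    beta: pd.Series  # common covariate effects
    baseline: pd.Series  # per-taxon baseline log-abundance
    taxon_slopes: pd.DataFrame  # b: taxa x predictors
    individual_slopes: pd.DataFrame  # c: individuals x predictors
    taxon_individual_slopes: pd.DataFrame  # d: (taxon|individual) x predictors
    individual_intercepts: pd.Series  # u
    taxon_intercepts: pd.Series  # v
    sample_intercepts: pd.Series  # w
    latent: pd.DataFrame  # realized latent log-abundance, samples x taxa
    clr_slopes: pd.DataFrame = None  # identifiable truth: (beta + b) centered over taxa

    def __post_init__(self):
        if self.clr_slopes is None:
            total = self.taxon_slopes.add(self.beta, axis=1)
            self.clr_slopes = total - total.mean(axis=0)

    def to_json(self) -> str:
        payload = {
            "beta": self.beta.to_dict(),
            "baseline": self.baseline.to_dict(),
            "taxon_slopes": self.taxon_slopes.to_dict(orient="index"),
            "individual_slopes": self.individual_slopes.to_dict(orient="index"),
            "taxon_individual_slopes": self.taxon_individual_slopes.to_dict(orient="index"),
            "individual_intercepts": self.individual_intercepts.to_dict(),
            "taxon_intercepts": self.taxon_intercepts.to_dict(),
            "sample_intercepts": self.sample_intercepts.to_dict(),
            "latent": self.latent.to_dict(orient="index"),
            "clr_slopes": self.clr_slopes.to_dict(orient="index"),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            beta=pd.Series(d["beta"]),
            baseline=pd.Series(d["baseline"]),
            taxon_slopes=pd.DataFrame.from_dict(d["taxon_slopes"], orient="index"),
            individual_slopes=pd.DataFrame.from_dict(d["individual_slopes"], orient="index"),
            taxon_individual_slopes=pd.DataFrame.from_dict(
                d["taxon_individual_slopes"], orient="index"
            ),
            individual_intercepts=pd.Series(d["individual_intercepts"]),
            taxon_intercepts=pd.Series(d["taxon_intercepts"]),
            sample_intercepts=pd.Series(d["sample_intercepts"]),
            latent=pd.DataFrame.from_dict(d["latent"], orient="index"),
            clr_slopes=pd.DataFrame.from_dict(d["clr_slopes"], orient="index"),
        )


@dataclass
class StudyBundle:
    """A complete in-memory synthetic study."""

    config: SynthConfig
    table: CountTable
    metadata: pd.DataFrame
    behavior: pd.DataFrame
    climate: pd.DataFrame
    tree: TreeNode
    truth: TruthRecord


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _child_seed(seed: int, label: str) -> int:
    # stable per-stage substream, kept below 2**31
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths.

    Leaves are labelled ``taxon_1 .. taxon_n``; lineages are joined two at a
    time (random pairs), giving ``n - 1`` internal bifurcations.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = [f"taxon_{i + 1}:{rng.exponential(1.0):.6f}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    return TreeNode.read(_io.StringIO(newick), convert_underscores=False)


def _seasonal(month: np.ndarray, mean: float, amplitude: float, peak_month: int) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (month - peak_month) / 12.0)


def generate_covariates(config: SynthConfig, seed: int | None = None):
    """Seasonal behavior rates, monthly precipitation, and sample metadata.

    Precipitation follows a concentrated bump peaking mid rainy season
    (January) and near zero through the dry season — rain in such forests
    is not sinusoidal, and the sharper shape also keeps the five covariates
    from being collinear (any three same-period sinusoids are linearly
    dependent). Fruit feeding peaks in the rainy season (February), leaf
    feeding in the dry season (July), flowers at the late-dry transition
    (November), affiliation mid dry season (May). Noise is truncated at
    zero so rates stay non-negative.

    Returns ``(behavior, climate, metadata)`` frames matching the on-disk
    dialects.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    months = np.arange(1, config.n_months + 1)
    cal_months = ((months - 1) % 12) + 1

    bump = np.maximum(0.0, np.cos(2.0 * np.pi * (cal_months - 1) / 12.0)) ** 2
    precip = config.precip_dry_mean + (
        config.precip_rainy_mean - config.precip_dry_mean
    ) * bump
    precip = np.maximum(0.0, precip + rng.normal(0.0, config.precip_noise, len(months)))
    climate = pd.DataFrame({"month": cal_months, "precipitation_mm": precip})

    individuals = [f"I{i + 1}" for i in range(config.n_individuals)]
    templates = {
        "fruit_rate": (config.fruit_mean, config.fruit_amplitude, 2),
        "leaf_rate": (config.leaf_mean, config.leaf_amplitude, 7),
        "flower_rate": (config.flower_mean, config.flower_amplitude, 11),
        "affiliation_rate": (config.affiliation_mean, config.affiliation_amplitude, 5),
    }
    rows = []
    for ind in individuals:
        for m in cal_months:
            row = {"individual_id": ind, "month": int(m)}
            for col, (mean, amp, peak) in templates.items():
                value = _seasonal(np.array([m]), mean, amp, peak)[0]
                row[col] = max(0.0, value + rng.normal(0.0, config.behavior_noise))
            rows.append(row)
    behavior = pd.DataFrame(rows)

    meta_rows = []
    days = np.linspace(5, 25, config.samples_per_month).round().astype(int)
    for ind in individuals:
        for m in cal_months:
            for r in range(config.samples_per_month):
                meta_rows.append(
                    {
                        "sample_id": f"{ind}_m{m:02d}_{r + 1}",
                        "individual_id": ind,
                        "date": pd.Timestamp(config.year, int(m), int(days[r])),
                        "fraction": "entire",
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    metadata["month"] = metadata["date"].dt.month
    metadata["season"] = metadata["month"].map(assign_season)
    return behavior, climate, metadata


def generate_counts(
    config: SynthConfig,
    behavior: pd.DataFrame,
    climate: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int | None = None,
) -> tuple[CountTable, TruthRecord]:
    """Draw a count table from the latent Gaussian log-linear model."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{t + 1}" for t in range(config.n_taxa)]
    individuals = sorted(behavior["individual_id"].unique())
    samples = metadata["sample_id"].tolist()
    T, P = config.n_taxa, len(PREDICTORS)

    cov = behavior.merge(climate, on="month", how="left")
    if cov["precipitation_mm"].isna().any():
        raise ValueError("climate does not cover every behavior month")
    cov = cov.set_index(["individual_id", "month"])
    x = np.empty((len(samples), P))
    for si, row in enumerate(metadata.itertuples()):
        cell = cov.loc[(row.individual_id, row.month)]
        x[si] = [cell[p] for p in PREDICTORS]

    beta = pd.Series({p: config.beta[p] for p in PREDICTORS})
    baseline = pd.Series(rng.normal(0.0, config.baseline_sd, T), index=taxa)
    b = pd.DataFrame(
        rng.normal(0.0, 1.0, (T, P)) * [config.tau[p] for p in PREDICTORS],
        index=taxa,
        columns=PREDICTORS,
    )
    c = pd.DataFrame(
        rng.normal(0.0, 1.0, (len(individuals), P))
        * [config.individual_slope_sd[p] for p in PREDICTORS],
        index=individuals,
        columns=PREDICTORS,
    )
    ti_index = [f"{t}|{i}" for t in taxa for i in individuals]
    d = pd.DataFrame(
        rng.normal(0.0, 1.0, (len(ti_index), P))
        * [config.taxon_individual_slope_sd[p] for p in PREDICTORS],
        index=ti_index,
        columns=PREDICTORS,
    )
    u = pd.Series(rng.normal(0.0, config.individual_sd, len(individuals)), index=individuals)
    v = pd.Series(rng.normal(0.0, config.taxon_sd, T), index=taxa)
    w = pd.Series(rng.normal(0.0, config.sample_sd, len(samples)), index=samples)

    latent = np.empty((len(samples), T))
    for si, row in enumerate(metadata.itertuples()):
        ind = row.individual_id
        slopes = (
            beta.to_numpy()[None, :]
            + b.to_numpy()
            + c.loc[ind].to_numpy()[None, :]
            + d.loc[[f"{t}|{ind}" for t in taxa]].to_numpy()
        )
        latent[si] = (
            baseline.to_numpy()
            + v.to_numpy()
            + u[ind]
            + w.iloc[si]
            + slopes @ x[si]
            + rng.normal(0.0, config.residual_sd, T)
        )
        if config.season_evenness_effect and assign_season(int(row.month)) == "rainy":
            center = latent[si].mean()
            latent[si] = center + (1.0 + config.season_evenness_effect) * (
                latent[si] - center
            )

    logits = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    shape = config.depth_dispersion
    depths = rng.negative_binomial(shape, shape / (shape + config.depth_mean), len(samples))
    depths = np.maximum(depths, 1)
    counts = np.vstack([rng.multinomial(n, p) for n, p in zip(depths, probs)])

    table = CountTable(tuple(samples), tuple(taxa), counts.astype(float))
    truth = TruthRecord(
        beta=beta,
        baseline=baseline,
        taxon_slopes=b,
        individual_slopes=c,
        taxon_individual_slopes=d,
        individual_intercepts=u,
        taxon_intercepts=v,
        sample_intercepts=w,
        latent=pd.DataFrame(latent, index=samples, columns=taxa),
    )
    return table, truth


def generate_study(config: SynthConfig | None = None) -> StudyBundle:
    """Compose tree, covariates, and counts into a full study bundle."""
    if config is None:
        config = SynthConfig()
    tree = generate_tree(config.n_taxa, seed=_child_seed(config.seed, "tree"))
    behavior, climate, metadata = generate_covariates(
        config, seed=_child_seed(config.seed, "covariates")
    )
    table, truth = generate_counts(
        config, behavior, climate, metadata, seed=_child_seed(config.seed, "counts")
    )
    return StudyBundle(config, table, metadata, behavior, climate, tree, truth)


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(bundle.table, out / "counts.tsv")
    write_metadata(bundle.metadata, out / "metadata.csv")
    write_behavior(bundle.behavior, out / "behavior.csv")
    write_climate(bundle.climate, out / "climate.csv")
    bundle.tree.write(str(out / "tree.nwk"), format="newick")
    (out / "truth.json").write_text(bundle.truth.to_json())
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
    return out


def load_bundle(path) -> StudyBundle:
    path = Path(path)
    config = SynthConfig.from_yaml(path / "config.yaml")
    return StudyBundle(
        config=config,
        table=read_count_table(path / "counts.tsv"),
        metadata=read_metadata(path / "metadata.csv"),
        behavior=read_behavior(path / "behavior.csv"),
        climate=read_climate(path / "climate.csv"),
        tree=read_newick(path / "tree.nwk"),
        truth=TruthRecord.from_json((path / "truth.json").read_text()),
    )
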