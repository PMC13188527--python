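"""Seed-reproducible synthetic cohorts for a murine oral-carcinogenesis
microbiome study.

The generator emulates a two-genotype (WT vs Dmbt1-knockout), two-sex cohort
sampled at weeks 0, 4, 8, 12, 16 and 22 after carcinogen initiation, with an
endpoint histopathology label (ED/CIS vs OSCC) applied to every visit of a
mouse.  Counts come from a latent additive model on the log scale:

    a[s, k] = baseline[k] + sum(active effects)[s, k] + b[mouse(s), k] + eps[s, k]

with a mouse-level random intercept b (compound-symmetry correlation across
a mouse's visits) and iid residual noise, mapped through a softmax and a
multinomial draw at the sample's library size.  Structural zeros are
host-level: a (mouse, OTU) pair flagged absent contributes nothing at any
visit.  Effects are additive on the log scale, so downstream CLR analyses
see them (up to the CLR centering) as the injected profiles.

Two independent RNG streams are used: the *assignment* stream fixes cohort
structure (arms, diagnoses, visit masks, baselines, structural zeros,
taxonomy) and the *counts* stream fixes the stochastic realization (random
intercepts, noise, depths, multinomial draws), so injecting a mean effect
never perturbs cohort structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import RANKS, OtuCountTable
from . import tables

DEFAULT_WEEKS = (0, 4, 8, 12, 16, 22)

#: (genotype, sex) -> arm size; mirrors the study's 22/13/20/21 layout
DEFAULT_ARMS = {
    ("WT", "M"): 22,
    ("KO", "M"): 13,
    ("WT", "F"): 20,
    ("KO", "F"): 21,
}

COVARIATES = ("genotype", "diagnosis", "interaction", "sex")

# small pool of oral/murine taxa for plausible synthetic lineages
_FAMILY_POOL = [
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae",
     ["Blautia", "Roseburia", "unclassified"]),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae",
     ["Streptococcus", "Lactococcus"]),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae",
     ["Lactobacillus", "unclassified"]),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae",
     ["Granulicatella", "unclassified"]),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pasteurellales",
     "Pasteurellaceae", ["Haemophilus", "Aggregatibacter", "unclassified"]),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
     "Sphingomonadaceae", ["Sphingomonas"]),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
     "Bradyrhizobiaceae", ["Bradyrhizobium"]),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
     "Comamonadaceae", ["Delftia", "unclassified"]),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
     "Oxalobacteraceae", ["Ralstonia", "Cupriavidus"]),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Porphyromonadaceae", ["Porphyromonas", "unclassified"]),
    ("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales",
     "Flavobacteriaceae", ["Capnocytophaga", "unclassified"]),
    ("Bacteria", "Actinobacteria", "Actinobacteria", "Actinomycetales",
     "Micrococcaceae", ["Rothia", "unclassified"]),
    ("Bacteria", "Candidatus_Saccharibacteria", "unclassified", "unclassified",
     "unclassified", ["unclassified"]),
    ("Bacteria", "Fusobacteria", "Fusobacteriia", "Fusobacteriales",
     "Fusobacteriaceae", ["Fusobacterium"]),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae",
     ["Ruminococcus", "unclassified"]),
]


@dataclass
class StudyDesign:
    """Cohort layout: arms, visit grid, community size, sequencing depth."""

    n_mice: dict = field(default_factory=lambda: dict(DEFAULT_ARMS))
    weeks: tuple = DEFAULT_WEEKS
    n_otus: int = 200
    depth_mean: float = 20000.0
    dropout_rate: float = 0.10
    diagnosis_model: dict = field(
        default_factory=lambda: {"WT": 0.25, "KO": 0.55}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        weeks = tuple(int(w) for w in self.weeks)
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        self.weeks = weeks
        if self.n_otus < 10:
            raise ValueError("n_otus must be >= 10")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for g, p in self.diagnosis_model.items():
            if not 0 <= p <= 1:
                raise ValueError(f"diagnosis probability for {g} outside [0, 1]")

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def total_mice(self) -> int:
        return int(sum(self.n_mice.values()))


@dataclass
class EffectProfile:
    """A time-localized covariate effect on the latent log scale."""

    otu_index: int
    covariate: str
    profile: np.ndarray
    conditioning: dict | None = None

    def __post_init__(self) -> None:
        if self.covariate not in COVARIATES:
            raise ValueError(f"covariate must be one of {COVARIATES}")
        self.profile = np.asarray(self.profile, dtype=float)

    def key(self) -> tuple:
        cond = tuple(sorted(self.conditioning.items())) if self.conditioning else ()
        return (self.otu_index, self.covariate, cond)

    def indicator(self, assignments: pd.DataFrame) -> np.ndarray:
        """Per-mouse 0/1 indicator for this effect's covariate x conditioning."""
        geno_ko = (assignments["genotype"] == "KO").to_numpy()
        oscc = (assignments["diagnosis"] == "OSCC").to_numpy()
        female = (assignments["sex"] == "F").to_numpy()
        if self.covariate == "genotype":
            ind = geno_ko
        elif self.covariate == "diagnosis":
            ind = oscc
        elif self.covariate == "interaction":
            ind = geno_ko & oscc
        else:
            ind = female
        ind = ind.astype(float)
        if self.conditioning:
            for col, val in self.conditioning.items():
                ind = ind * (assignments[col] == val).to_numpy(dtype=float)
        return ind


@dataclass
class TruthConfig:
    """Generator parameters not fixed by the study design."""

    sigma_b: float = 0.7
    sigma_e: float = 1.0
    baseline_sd: float = 2.0
    zero_inflation: float | np.ndarray = 0.3
    effects: list = field(default_factory=list)
    on_insufficient_visits: str = "regenerate"  # or "raise"


@dataclass
class SimulationTruth:
    """Everything needed to audit or exactly regenerate a cohort."""

    design: StudyDesign
    baseline_log_abundances: np.ndarray
    mouse_random_effect_sd: float
    residual_sd: float
    zero_inflation: np.ndarray
    effects: list
    assignments: pd.DataFrame  # index mouse_id: genotype, sex, diagnosis
    visit_mask: pd.DataFrame  # mouse x week booleans
    structural_zero: pd.DataFrame | None = None  # mouse x otu booleans
    latent: pd.DataFrame | None = None  # sample x otu latent log-abundance
    config: TruthConfig | None = None


def _mouse_frame(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for (geno, sex), n in sorted(design.n_mice.items()):
        for _ in range(int(n)):
            p = design.diagnosis_model.get(geno, 0.5)
            diag = "OSCC" if rng.random() < p else "ED/CIS"
            rows.append((f"M{i:03d}", geno, sex, diag))
            i += 1
    return pd.DataFrame(
        rows, columns=["mouse_id", "genotype", "sex", "diagnosis"]
    ).set_index("mouse_id")


def _visit_mask(
    design: StudyDesign, mice: pd.Index, rng: np.random.Generator, mode: str
) -> pd.DataFrame:
    mask = np.ones((len(mice), design.n_weeks), dtype=bool)
    if design.dropout_rate > 0:
        for i in range(len(mice)):
            row = rng.random(design.n_weeks) >= design.dropout_rate
            while row.sum() < 2:
                if mode == "raise":
                    raise ValueError(f"mouse {mice[i]} left with < 2 visits")
                row = rng.random(design.n_weeks) >= design.dropout_rate
            mask[i] = row
    return pd.DataFrame(mask, index=mice, columns=list(design.weeks))


def _taxonomy(n_otus: int, rng: np.random.Generator) -> pd.Series:
    lineages = {}
    for k in range(n_otus):
        dom, phy, cls, order, fam, genera = _FAMILY_POOL[
            rng.integers(len(_FAMILY_POOL))
        ]
        genus = genera[rng.integers(len(genera))]
        lineages[f"Otu{k + 1:04d}"] = (dom, phy, cls, order, fam, genus)
    return pd.Series(lineages)


def build_truth(design: StudyDesign, config: TruthConfig | None = None) -> SimulationTruth:
    """Draw the cohort structure (assignment RNG stream only)."""
    config = config or TruthConfig()
    if config.sigma_b < 0 or config.sigma_e <= 0:
        raise ValueError("need sigma_b >= 0 and sigma_e > 0")
    rng = np.random.default_rng([int(design.seed), 1])
    assignments = _mouse_frame(design, rng)
    mask = _visit_mask(design, assignments.index, rng, config.on_insufficient_visits)
    baseline = rng.normal(0.0, config.baseline_sd, design.n_otus)
    zi = np.broadcast_to(
        np.asarray(config.zero_inflation, dtype=float), (design.n_otus,)
    ).copy()
    if ((zi < 0) | (zi >= 1)).any():
        raise ValueError("zero_inflation must be in [0, 1)")
    structural = rng.random((len(assignments), design.n_otus)) < zi[None, :]
    otus = [f"Otu{k + 1:04d}" for k in range(design.n_otus)]
    for eff in config.effects:
        _check_effect(design, eff)
    return SimulationTruth(
        design=design,
        baseline_log_abundances=baseline,
        mouse_random_effect_sd=float(config.sigma_b),
        residual_sd=float(config.sigma_e),
        zero_inflation=zi,
        effects=list(config.effects),
        assignments=assignments,
        visit_mask=mask,
        structural_zero=pd.DataFrame(structural, index=assignments.index, columns=otus),
        config=config,
    )


def _check_effect(design: StudyDesign, effect: EffectProfile) -> None:
    if not 0 <= effect.otu_index < design.n_otus:
        raise IndexError(f"otu_index {effect.otu_index} out of range")
    if effect.profile.shape != (design.n_weeks,):
        raise ValueError(
            f"profile length {effect.profile.shape[0]} != {design.n_weeks} weeks"
        )


def inject_effect(truth, effect: EffectProfile):
    """Return a copy of a truth/config with one more effect profile.

    Duplicate (otu, covariate, conditioning) triples are rejected.
    """
    if isinstance(truth, SimulationTruth):
        _check_effect(truth.design, effect)
        if effect.key() in {e.key() for e in truth.effects}:
            raise ValueError(f"duplicate effect {effect.key()}")
        out = dataclasses.replace(truth, effects=truth.effects + [effect])
        if out.config is not None:
            out.config = dataclasses.replace(
                out.config, effects=list(out.effects)
            )
        return out
    if isinstance(truth, TruthConfig):
        if effect.key() in {e.key() for e in truth.effects}:
            raise ValueError(f"duplicate effect {effect.key()}")
        return dataclasses.replace(truth, effects=truth.effects + [effect])
    raise TypeError("expected SimulationTruth or TruthConfig")


def latent_matrix(truth: SimulationTruth, rng: np.random.Generator | None = None):
    """Latent log-abundance per observed sample; also returns sample metadata.

    When ``rng`` is None only the deterministic mean part (baseline + effects)
    is returned: random intercepts and residual noise are drawn from ``rng``.
    """
    design = truth.design
    mice = truth.assignments.index
    n_mice, n_otus, n_weeks = len(mice), design.n_otus, design.n_weeks

    mean = np.tile(truth.baseline_log_abundances, (n_mice, n_weeks, 1))
    for eff in truth.effects:
        ind = eff.indicator(truth.assignments)  # n_mice
        mean[:, :, eff.otu_index] += ind[:, None] * eff.profile[None, :]

    if rng is not None:
        b = rng.normal(0.0, truth.mouse_random_effect_sd, (n_mice, n_otus))
        eps = rng.normal(0.0, truth.residual_sd, (n_mice, n_weeks, n_otus))
        mean = mean + b[:, None, :] + eps

    rows, meta = [], []
    mask = truth.visit_mask.to_numpy()
    for i, mouse in enumerate(mice):
        for j, week in enumerate(design.weeks):
            if mask[i, j]:
                rows.append(mean[i, j])
                meta.append((f"{mouse}_w{week:02d}", mouse, week))
    latent = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index([m[0] for m in meta], name="sample_id"),
        columns=[f"Otu{k + 1:04d}" for k in range(n_otus)],
    )
    sample_meta = pd.DataFrame(
        meta, columns=["sample_id", "mouse_id", "week"]
    ).set_index("sample_id")
    return latent, sample_meta


def generate_cohort(
    design: StudyDesign, truth_config: TruthConfig | SimulationTruth | None = None
) -> tuple[OtuCountTable, SimulationTruth]:
    """Generate a full synthetic cohort.

    ``truth_config`` may be a :class:`TruthConfig` (structure drawn fresh from
    the design's seed) or a previously built :class:`SimulationTruth`, which
    is reused verbatim so a reloaded truth reproduces the identical table.
    """
    if isinstance(truth_config, SimulationTruth):
        truth = truth_config
    else:
        truth = build_truth(design, truth_config)
    rng_counts = np.random.default_rng([int(design.seed), 2])

    latent, sample_meta = latent_matrix(truth, rng_counts)
    # structural zeros: host-level absence, excluded from the softmax support
    absent = truth.structural_zero.loc[sample_meta["mouse_id"]].to_numpy()
    logits = latent.to_numpy().copy()
    logits[absent] = -np.inf

    n_samples = logits.shape[0]
    depths = rng_counts.poisson(design.depth_mean, n_samples)
    depths = np.maximum(depths, 1)
    counts = np.zeros_like(logits, dtype=np.int64)
    for i in range(n_samples):
        row = logits[i]
        finite = np.isfinite(row)
        p = np.zeros(row.size)
        ex = np.exp(row[finite] - row[finite].max())
        p[finite] = ex / ex.sum()
        counts[i] = rng_counts.multinomial(depths[i], p)

    taxonomy = _taxonomy(design.n_otus, np.random.default_rng([int(design.seed), 3]))
    meta = sample_meta.join(truth.assignments, on="mouse_id")
    meta = meta[["mouse_id", "genotype", "sex", "week", "diagnosis"]]
    table = OtuCountTable(
        counts=pd.DataFrame(counts, index=latent.index, columns=latent.columns),
        sample_meta=meta,
        taxonomy=taxonomy,
    )
    truth.latent = latent
    return table, truth


# ---------------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------------


def _design_to_dict(design: StudyDesign) -> dict:
    d = dataclasses.asdict(design)
    d["n_mice"] = {f"{g}|{s}": int(n) for (g, s), n in design.n_mice.items()}
    d["weeks"] = list(design.weeks)
    return d


def _design_from_dict(d: dict) -> StudyDesign:
    d = dict(d)
    d["n_mice"] = {tuple(k.split("|")): v for k, v in d["n_mice"].items()}
    d["weeks"] = tuple(d["weeks"])
    return StudyDesign(**d)


def truth_to_json(truth: SimulationTruth) -> dict:
    cfg = truth.config or TruthConfig(
        sigma_b=truth.mouse_random_effect_sd, sigma_e=truth.residual_sd
    )
    return {
        "design": _design_to_dict(truth.design),
        "sigma_b": truth.mouse_random_effect_sd,
        "sigma_e": truth.residual_sd,
        "baseline_sd": cfg.baseline_sd,
        "zero_inflation": truth.zero_inflation.tolist(),
        "on_insufficient_visits": cfg.on_insufficient_visits,
        "effects": [
            {
                "otu_index": e.otu_index,
                "covariate": e.covariate,
                "profile": e.profile.tolist(),
                "conditioning": e.conditioning,
            }
            for e in truth.effects
        ],
    }


def truth_from_json(d: dict) -> tuple[StudyDesign, TruthConfig]:
    design = _design_from_dict(d["design"])
    effects = [
        EffectProfile(
            otu_index=e["otu_index"],
            covariate=e["covariate"],
            profile=np.asarray(e["profile"]),
            conditioning=e["conditioning"],
        )
        for e in d["effects"]
    ]
    config = TruthConfig(
        sigma_b=d["sigma_b"],
        sigma_e=d["sigma_e"],
        baseline_sd=d["baseline_sd"],
        zero_inflation=np.asarray(d["zero_inflation"]),
        effects=effects,
        on_insufficient_visits=d["on_insufficient_visits"],
    )
    return design, config


def write_fixture(table: OtuCountTable, truth: SimulationTruth, directory) -> dict:
    """Write mothur-dialect .shared/.cons.taxonomy, metadata TSV, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "shared": directory / "cohort.shared",
        "taxonomy": directory / "cohort.cons.taxonomy",
        "metadata": directory / "cohort.metadata.tsv",
        "truth": directory / "cohort.truth.json",
    }
    tables.write_shared(table.counts, paths["shared"])
    sizes = table.counts.sum(axis=0)
    tables.write_cons_taxonomy(table.taxonomy, sizes, paths["taxonomy"])
    tables.write_metadata(table.sample_meta, paths["metadata"])
    paths["truth"].write_text(json.dumps(truth_to_json(truth), indent=2))
    return paths
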