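"""Synthetic paired transcript/protein cohorts.

The generator emulates the data structure the analysis assumes: two cohorts
of lymphoblast-like samples, a transcript count matrix over a large gene
universe, a much smaller protein intensity matrix with intensity-dependent
(missing-not-at-random) non-detection, and functional gene sets with planted
per-set, per-ome fold-changes — respiratory complexes I-IV with transcripts
down but proteins up, complex V and the ribosome down in both omes, immune
and sphingolipid sets up in both.

Transcripts: per-gene baseline abundances are log-normal; each sample draws
a library size uniformly from a range and counts are negative binomial with
a common dispersion around length-free expected counts proportional to gene
abundance. Case samples have their set genes' means multiplied by the set's
transcript fold-change.

Proteins: log intensities are normal around a per-protein baseline with
added sample noise; case samples are shifted by log(protein fold-change); a
cell is detected with logistic probability in its log intensity, so dim
proteins go missing more often — reproducing why intensity-based MS detects
an order of magnitude fewer features than RNA-seq.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    PROTEIN,
    TRANSCRIPT,
    CohortDesign,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)


@dataclass(frozen=True)
class SetEffect:
    """A planted gene set: `size` transcript members, of which the first
    `protein_size` are also observable in the proteome."""

    name: str
    size: int
    transcript_fc: float
    protein_fc: float
    protein_size: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("set size must be >= 1")
        if self.transcript_fc <= 0 or self.protein_fc <= 0:
            raise ValueError("fold-change multipliers must be positive")
        p = self.size if self.protein_size is None else self.protein_size
        if not 0 <= p <= self.size:
            raise ValueError("protein_size must be between 0 and size")

    @property
    def n_protein(self) -> int:
        return self.size if self.protein_size is None else self.protein_size


@dataclass
class SyntheticScenario:
    """Full generative configuration for one paired cohort.

    Defaults mirror the study shape at tractable scale: 20 cases vs 20
    controls, a few thousand background genes of which a fraction carry
    through to the proteome, library sizes around 130k reads, NB dispersion
    0.1, and log-normal protein intensities with logistic MNAR detection.
    """

    n_case: int = 20
    n_control: int = 20
    n_background_genes: int = 2000
    n_background_proteins: int = 1200
    sets: list[SetEffect] = field(default_factory=list)
    nb_dispersion: float = 0.1
    mean_log_expression: float = 3.0
    sd_log_expression: float = 1.2
    library_size_range: tuple[int, int] = (100_000, 160_000)
    mean_log_intensity: float = 21.0
    sd_log_intensity: float = 1.5
    noise_sd_protein: float = 0.4
    protein_detection_midpoint: float = 19.5
    protein_detection_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_background_genes < 0 or self.n_background_proteins < 0:
            raise ValueError("background sizes must be nonnegative")
        if self.n_background_proteins > self.n_background_genes:
            raise ValueError("background proteins cannot exceed background genes")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.noise_sd_protein < 0 or self.sd_log_expression < 0:
            raise ValueError("noise scales must be >= 0")
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names in scenario")


def default_scenario(**overrides) -> SyntheticScenario:
    """The study-shaped scenario: set sizes follow the detected-member
    counts of the mitochondrial functional groups (44 Complex I transcripts
    of which 26 are proteome-observable, and so on), respiratory complexes
    I-IV planted transcript-down/protein-up (0.8 / 2.0), Complex V and the
    ribosome down in both omes (0.8 / 0.8), TCA and import machinery
    protein-up, immune and sphingolipid sets up in both."""
    sets = [
        SetEffect("CI", 44, 0.8, 2.0, protein_size=26),
        SetEffect("CII", 8, 0.8, 2.0, protein_size=2),
        SetEffect("CIII", 11, 0.8, 2.0, protein_size=9),
        SetEffect("CIV", 35, 0.8, 2.0, protein_size=10),
        SetEffect("CV", 19, 0.8, 0.8, protein_size=12),
        SetEffect("TCA", 24, 1.0, 1.8, protein_size=24),
        SetEffect("SLC25", 52, 0.9, 1.0, protein_size=11),
        SetEffect("TIMM_TOMM", 23, 0.9, 1.5, protein_size=9),
        SetEffect("RIBOSOME", 80, 0.8, 0.8, protein_size=50),
        SetEffect("IMMUNE", 60, 1.5, 1.5, protein_size=40),
        SetEffect("SPHINGOLIPID", 30, 1.5, 1.5, protein_size=15),
    ]
    return SyntheticScenario(sets=sets, **overrides)


def null_scenario(n_case: int = 10, n_control: int = 10,
                  n_background_genes: int = 500,
                  n_background_proteins: int = 500,
                  **overrides) -> SyntheticScenario:
    """No planted effects: every gene's multipliers are 1 in both omes.
    Library depth is scaled with the smaller gene universe so per-gene
    counts stay in the same regime as the default scenario."""
    overrides.setdefault("library_size_range", (30_000, 45_000))
    return SyntheticScenario(n_case=n_case, n_control=n_control,
                             n_background_genes=n_background_genes,
                             n_background_proteins=n_background_proteins,
                             sets=[], **overrides)


def generate_cohort(scenario: SyntheticScenario, seed: int | None = None):
    """Draw one paired cohort.

    Returns ``(transcripts, proteins, design, gene_sets)`` where the two
    matrices are :class:`ExpressionMatrix` objects sharing a feature-id
    space, the design covers all samples, and the gene sets (category
    ``functional_group``) list each planted set's transcript members.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n1, n2 = scenario.n_case, scenario.n_control
    samples = [f"case_{i+1:02d}" for i in range(n1)] + \
              [f"ctrl_{i+1:02d}" for i in range(n2)]
    design = CohortDesign({s: ("case" if s.startswith("case") else "control")
                           for s in samples})

    gene_ids, t_fc, p_fc, is_protein, set_members = [], [], [], [], {}
    for s in scenario.sets:
        ids = [f"{s.name}_{i+1:03d}" for i in range(s.size)]
        gene_ids += ids
        t_fc += [s.transcript_fc] * s.size
        p_fc += [s.protein_fc] * s.size
        is_protein += [i < s.n_protein for i in range(s.size)]
        set_members[s.name] = ids
    bg = [f"BG_{i+1:05d}" for i in range(scenario.n_background_genes)]
    gene_ids += bg
    t_fc += [1.0] * len(bg)
    p_fc += [1.0] * len(bg)
    is_protein += [i < scenario.n_background_proteins for i in range(len(bg))]

    t_fc = np.asarray(t_fc)
    p_fc = np.asarray(p_fc)
    is_protein = np.asarray(is_protein, dtype=bool)
    n_genes = len(gene_ids)

    # --- transcripts -------------------------------------------------------
    base = rng.lognormal(scenario.mean_log_expression,
                         scenario.sd_log_expression, n_genes)
    rel = base / base.sum()
    lo, hi = scenario.library_size_range
    lib = rng.integers(lo, hi + 1, size=n1 + n2)
    mu = rel[:, None] * lib[None, :]
    mu[:, :n1] *= t_fc[:, None]
    if scenario.nb_dispersion > 0:
        shape = 1.0 / scenario.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    transcripts = ExpressionMatrix(
        ome=TRANSCRIPT,
        values=pd.DataFrame(counts.astype(float), index=gene_ids,
                            columns=samples),
        feature_length_bp=pd.Series(
            rng.integers(300, 10_000, size=n_genes).astype(float),
            index=gene_ids),
    )

    # --- proteins ----------------------------------------------------------
    prot_ids = [g for g, ok in zip(gene_ids, is_protein) if ok]
    mu_p = rng.normal(scenario.mean_log_intensity, scenario.sd_log_intensity,
                      len(prot_ids))
    log_i = mu_p[:, None] + rng.normal(
        0.0, scenario.noise_sd_protein, (len(prot_ids), n1 + n2))
    log_i[:, :n1] += np.log(p_fc[is_protein])[:, None]
    detect_p = 1.0 / (1.0 + np.exp(-scenario.protein_detection_slope
                                   * (log_i - scenario.protein_detection_midpoint)))
    detected = rng.random(log_i.shape) < detect_p
    intensities = np.where(detected, np.exp(log_i), np.nan)
    proteins = ExpressionMatrix(
        ome=PROTEIN,
        values=pd.DataFrame(intensities, index=prot_ids, columns=samples),
    )

    gene_sets = GeneSetCollection([
        GeneSet(name=name, category="functional_group",
                members=frozenset(ids))
        for name, ids in set_members.items()
    ])
    return transcripts, proteins, design, gene_sets


def scenario_from_dict(cfg: dict) -> SyntheticScenario:
    """Build a scenario from a YAML-style mapping (see the CLI docs)."""
    cfg = dict(cfg)
    sets = [SetEffect(**s) for s in cfg.pop("sets", [])]
    if "library_size_range" in cfg:
        cfg["library_size_range"] = tuple(cfg["library_size_range"])
    return SyntheticScenario(sets=sets, **cfg)


def scenario_to_dict(scenario: SyntheticScenario) -> dict:
    d = {k: v for k, v in vars(scenario).items() if k != "sets"}
    d["library_size_range"] = list(scenario.library_size_range)
    d["sets"] = [{"name": s.name, "size": s.size,
                  "transcript_fc": s.transcript_fc,
                  "protein_fc": s.protein_fc,
                  "protein_size": s.n_protein} for s in scenario.sets]
    return d
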