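"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators are provided:

* :func:`generate_screen` — well-level morphology tables emulating a
  high-content RNAi screen: 96-well plates restricted to the inner 60
  wells, >=3 scrambled-control wells per plate, 41 genes x 4-5 shRNAs x
  3 culture replicates x 3 fixation time points (DIV 7/14/21), additive
  batch / plate-within-batch / edge / DIV / residual variance components
  on the log2 scale, block-correlated parameters (synaptic staining
  intensities anti-correlated with puncta densities), and per-gene effect
  archetypes scaled by per-shRNA knockdown efficacy.
* :func:`generate_proteomics` — protein x sample intensity tables with
  per-identification q-values, contaminant rows, optional outlier
  replicates, and regulated proteins planted with sign-concordant log2
  effects across all shRNAs of a gene.
* :func:`generate_network_and_annotations` — a weighted undirected edge
  list with a planted near-clique module against a sparse background,
  plus GMT-style annotation sets, standing in for STRING/gProfiler
  inputs so enrichment runs offline.

All generators are fully determined by their seed.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .params import (
    DENDRITIC_BLOCK,
    NUCLEAR_BLOCK,
    PARAMETERS,
    REPRESENTATIVE_PARAMETERS,
    SYNAPTIC_COUNT_BLOCK,
    SYNAPTIC_INTENSITY_BLOCK,
    TREATMENT_EXPERIMENTAL,
    TREATMENT_SCRAMBLED,
    TREATMENT_UNTREATED,
)


class ScreenConfigError(ValueError):
    """Raised when a screen design or simulation config is invalid."""


# ---------------------------------------------------------------------------
# Plate geometry: inner 60 wells of a 96-well plate (rows B-G, columns 2-11).
# The border of that inner block is flagged as "edge".
# ---------------------------------------------------------------------------

_INNER_ROWS = "BCDEFG"
_INNER_COLS = range(2, 12)

INNER_WELLS: tuple[str, ...] = tuple(
    f"{r}{c:02d}" for r in _INNER_ROWS for c in _INNER_COLS
)


def is_edge_well(well: str) -> bool:
    row, col = well[0], int(well[1:])
    return row in ("B", "G") or col in (2, 11)


# 41 candidate risk genes screened; the positive-control knockdown (Nlgn1)
# is carried as an ordinary gene and used only for plate QC.
DEFAULT_GENES: tuple[str, ...] = (
    "Adnp", "Ank2", "Arid1b", "Atp2a2", "Bcl11a", "C4a", "Cacna1c",
    "Cacna1d", "Cacna1i", "Cacna2d3", "Cacnb2", "Chd8", "Cntnap2", "Csmd1",
    "Cttnbp2", "Drd2", "Dyrk1a", "Fmr1", "Gabrb3", "Grm3", "Katnal2",
    "Kctd13", "Kmt2c", "Kmt5b", "Kynu", "Mecp2", "Mib1", "Nrxn1", "Pogz",
    "Pten", "Reln", "Scn2a", "Setd1a", "Shank3", "Stxbp1", "Stxbp5",
    "Syngap1", "Tbr1", "Tcf4", "Top3b", "Vipr2",
)


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of the screen: who is knocked down where, and when."""

    genes: tuple[str, ...] = DEFAULT_GENES
    shrnas_per_gene: tuple[int, int] = (4, 5)
    n_replicates: int = 3
    divs: tuple[int, ...] = (7, 14, 21)
    scrambled_wells_per_plate: int = 3
    positive_control_label: str = "Nlgn1"
    positive_control_wells_per_plate: int = 3
    untreated_wells_per_plate: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.shrnas_per_gene
        if not (1 <= lo <= hi):
            raise ScreenConfigError("shrnas_per_gene must be a valid range")
        if self.scrambled_wells_per_plate < 3:
            raise ScreenConfigError("each plate needs >= 3 scrambled wells")
        if self.n_replicates < 1 or not self.divs:
            raise ScreenConfigError("need >= 1 replicate and >= 1 DIV")
        if self.experimental_wells_per_plate < 1:
            raise ScreenConfigError(
                "control wells exceed the 60-well inner plate capacity"
            )

    @property
    def control_wells_per_plate(self) -> int:
        return (
            self.scrambled_wells_per_plate
            + self.positive_control_wells_per_plate
            + self.untreated_wells_per_plate
        )

    @property
    def experimental_wells_per_plate(self) -> int:
        return len(INNER_WELLS) - self.control_wells_per_plate

    def shrna_ids(self) -> dict[str, list[str]]:
        """shRNA identifiers per gene; genes alternate between 5 and 4 constructs."""
        lo, hi = self.shrnas_per_gene
        out: dict[str, list[str]] = {}
        for i, gene in enumerate(self.genes):
            n = hi if i % 2 == 0 else lo
            out[gene] = [f"{gene}_sh{j + 1}" for j in range(n)]
        return out


@dataclass(frozen=True)
class EffectArchetype:
    """A phenotype class: signed log2 effect directions per core parameter.

    ``direction`` maps the four representative parameters to a relative
    signed weight; ``ramp`` scales the effect at each successive time point
    (progressive onset). ``magnitude`` is the peak log2 effect of a fully
    effective shRNA.
    """

    label: str
    direction: Mapping[str, float]
    ramp: tuple[float, ...] = (0.5, 0.75, 1.0)
    magnitude: float = 0.85

    def effect(self, parameter: str, div_index: int, n_divs: int) -> float:
        ramp = self.ramp[min(div_index, len(self.ramp) - 1)]
        return self.magnitude * ramp * self._weight(parameter)

    def _weight(self, parameter: str) -> float:
        d = dict(self.direction)
        if parameter in d:
            return d[parameter]
        # Non-representative parameters track their block.
        syn = 0.5 * (
            d.get("presynaptic_puncta_density", 0.0)
            + d.get("postsynaptic_puncta_density", 0.0)
        )
        if parameter == "nuclei_count":
            return 0.9 * d.get("neuron_count", 0.0)
        if parameter == "branch_points_per_neuron":
            return 0.8 * d.get("dendrite_length_per_neuron", 0.0)
        if parameter == "primary_neurites_per_neuron":
            return 0.4 * d.get("dendrite_length_per_neuron", 0.0)
        if parameter == "colocalized_puncta_density":
            return syn
        if parameter in SYNAPTIC_INTENSITY_BLOCK:
            # Staining intensity moves opposite to puncta density.
            return -0.35 * syn
        return 0.0


#: The six phenotype classes planted by default. Archetype "0" is the
#: no-effect class. I-IV are reductions dominated by one parameter class
#: with equal mild off-target weights, so their centred profiles form a
#: regular tetrahedron in the 4-parameter shape space (pairwise Pearson
#: correlation exactly -1/3) — the most separable configuration
#: correlation-distance clustering admits: late neuron loss (I),
#: dendrite-led loss sparing neurons (II), presynaptic-led synapse loss
#: (III), postsynaptic-led synapse loss (IV). V is a weak, near-uniform
#: broad reduction without a marked shape; like its real-screen
#: counterpart it passes the effect gate but co-clusters with
#: gate-escaping null shRNAs.
DEFAULT_ARCHETYPES: dict[str, EffectArchetype] = {
    "0": EffectArchetype("0", {}, magnitude=0.0),
    "I": EffectArchetype(
        "I",
        {
            "neuron_count": -1.0,
            "dendrite_length_per_neuron": -0.12,
            "presynaptic_puncta_density": -0.12,
            "postsynaptic_puncta_density": -0.12,
        },
        ramp=(0.15, 0.5, 1.0),   # late-onset neuron loss
    ),
    "II": EffectArchetype(
        "II",
        {
            "neuron_count": -0.12,
            "dendrite_length_per_neuron": -1.0,
            "presynaptic_puncta_density": -0.12,
            "postsynaptic_puncta_density": -0.12,
        },
        ramp=(0.65, 0.85, 1.0),  # early and progressive
    ),
    "III": EffectArchetype(
        "III",
        {
            "neuron_count": -0.12,
            "dendrite_length_per_neuron": -0.12,
            "presynaptic_puncta_density": -1.0,
            "postsynaptic_puncta_density": -0.12,
        },
        ramp=(1.0, 1.0, 1.0),    # synapse loss present from DIV7
    ),
    "IV": EffectArchetype(
        "IV",
        {
            "neuron_count": -0.12,
            "dendrite_length_per_neuron": -0.12,
            "presynaptic_puncta_density": -0.12,
            "postsynaptic_puncta_density": -1.0,
        },
        ramp=(0.65, 0.85, 1.0),  # early and progressive synapse loss
    ),
    "V": EffectArchetype(
        "V",
        {
            "neuron_count": -0.5,
            "dendrite_length_per_neuron": -0.5,
            "presynaptic_puncta_density": -0.6,
            "postsynaptic_puncta_density": -0.5,
        },
        ramp=(0.4, 0.7, 1.0),
        magnitude=0.7,
    ),
}

#: Default gene -> archetype assignment: a dozen genes carry phenotypes
#: spanning all five classes, the positive control behaves like a strong
#: synaptic archetype, and the remaining genes are planted null.
DEFAULT_GENE_ARCHETYPES: dict[str, str] = {
    "Kmt2c": "I", "Adnp": "I", "Dyrk1a": "I",
    "Drd2": "II", "Ank2": "II", "Stxbp1": "II", "Mib1": "II", "Reln": "II",
    "Mecp2": "III", "Shank3": "III",
    "Tcf4": "IV", "Tbr1": "IV", "Top3b": "IV", "Vipr2": "IV",
    "Stxbp5": "V",
    "Nlgn1": "IV",
}

#: Raw-scale per-well baselines for the 10 parameters (counts, counts/neuron,
#: um, puncta/um and arbitrary staining intensity units).
DEFAULT_BASELINES: dict[str, float] = {
    "nuclei_count": 3000.0,
    "neuron_count": 1500.0,
    "primary_neurites_per_neuron": 4.0,
    "branch_points_per_neuron": 8.0,
    "dendrite_length_per_neuron": 1800.0,
    "presynaptic_puncta_density": 0.45,
    "presynaptic_intensity": 850.0,
    "postsynaptic_puncta_density": 0.40,
    "postsynaptic_intensity": 700.0,
    "colocalized_puncta_density": 0.25,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic screen."""

    design: ScreenDesign = field(default_factory=ScreenDesign)
    #: Log2-scale standard deviations of the additive variance components.
    sd_batch: float = 0.05
    sd_plate: float = 0.08
    sd_edge: float = 0.06
    sd_div: float = 0.05
    sd_shrna: float = 0.0
    sd_residual: float = 0.15
    #: Within-block parameter correlation and the density/intensity
    #: anti-correlation of the residual noise.
    rho_block: float = 0.6
    rho_anti: float = -0.4
    rho_background: float = 0.1
    #: Deterministic maturation trend (dendritic/synaptic parameters grow
    #: with DIV on the raw scale); disable for pure variance-recovery runs.
    div_trend: bool = True
    archetypes: Mapping[str, EffectArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    gene_archetypes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GENE_ARCHETYPES)
    )
    efficacy_range: tuple[float, float] = (0.5, 1.0)
    dud_fraction: float = 0.1
    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_batch", "sd_plate", "sd_edge", "sd_div", "sd_shrna",
                     "sd_residual"):
            if getattr(self, name) < 0:
                raise ScreenConfigError(f"{name} must be >= 0")
        lo, hi = self.efficacy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ScreenConfigError("efficacy_range must lie within [0, 1]")
        if not (0.0 <= self.dud_fraction <= 1.0):
            raise ScreenConfigError("dud_fraction must lie within [0, 1]")


def _residual_correlation(cfg: SimulationConfig) -> np.ndarray:
    """Block correlation matrix of the residual noise, forced PSD."""
    p = len(PARAMETERS)
    idx = {name: i for i, name in enumerate(PARAMETERS)}
    corr = np.full((p, p), cfg.rho_background)
    blocks = (
        NUCLEAR_BLOCK,
        DENDRITIC_BLOCK,
        SYNAPTIC_COUNT_BLOCK,
        SYNAPTIC_INTENSITY_BLOCK,
    )
    for block in blocks:
        for a, b in itertools.combinations(block, 2):
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = cfg.rho_block
    for a in SYNAPTIC_COUNT_BLOCK:
        for b in SYNAPTIC_INTENSITY_BLOCK:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = cfg.rho_anti
    np.fill_diagonal(corr, 1.0)
    # Clip negative eigenvalues and restore the unit diagonal.
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


_DIV_TREND = {  # log2 increase per successive DIV for maturing parameters
    "dendrite_length_per_neuron": 0.5,
    "branch_points_per_neuron": 0.35,
    "presynaptic_puncta_density": 0.45,
    "postsynaptic_puncta_density": 0.45,
    "colocalized_puncta_density": 0.5,
}


def _layout_wells(design: ScreenDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every (gene, shRNA, DIV, replicate) cell to a plate position."""
    shrnas = design.shrna_ids()
    all_shrnas = [s for sids in shrnas.values() for s in sids]
    shrna_gene = {s: g for g, sids in shrnas.items() for s in sids}
    cap = design.experimental_wells_per_plate
    rows: list[dict] = []
    plate_counter = 0
    for rep in range(1, design.n_replicates + 1):
        batch = f"B{rep}"
        for div in design.divs:
            order = list(all_shrnas)
            rng.shuffle(order)
            chunks = [order[i:i + cap] for i in range(0, len(order), cap)]
            for chunk in chunks:
                plate_counter += 1
                plate = f"P{plate_counter:03d}"
                labels: list[tuple[str, str, str]] = []
                labels += [
                    ("scrambled", "", TREATMENT_SCRAMBLED)
                ] * design.scrambled_wells_per_plate
                pc = design.positive_control_label
                labels += [
                    (f"{pc}_sh1", pc, TREATMENT_EXPERIMENTAL)
                ] * design.positive_control_wells_per_plate
                labels += [
                    ("", "", TREATMENT_UNTREATED)
                ] * design.untreated_wells_per_plate
                labels += [
                    (s, shrna_gene[s], TREATMENT_EXPERIMENTAL) for s in chunk
                ]
                positions = list(INNER_WELLS)
                rng.shuffle(positions)
                for (shrna, gene, tclass), well in zip(labels, positions):
                    rows.append({
                        "batch": batch,
                        "plate": plate,
                        "well": well,
                        "is_edge": is_edge_well(well),
                        "div": div,
                        "shrna_id": shrna,
                        "gene": gene,
                        "treatment_class": tclass,
                        "replicate": rep,
                    })
    return pd.DataFrame(rows)


def generate_screen(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full well-level screen table on the raw measurement scale.

    Values are ``baseline * 2**x`` where ``x`` accumulates the planted
    variance components, the DIV maturation trend, the gene effect scaled
    by shRNA efficacy, and block-correlated Gaussian residual noise.
    Scrambled and untreated wells carry no gene effect.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    layout = _layout_wells(design, rng)

    p = len(PARAMETERS)
    batches = sorted(layout["batch"].unique())
    plates = sorted(layout["plate"].unique())
    divs = list(design.divs)
    shrna_gene = {
        s: g for g, sids in design.shrna_ids().items() for s in sids
    }
    pc = design.positive_control_label
    shrna_gene[f"{pc}_sh1"] = pc
    shrna_list = sorted(shrna_gene)

    b_batch = rng.normal(0.0, config.sd_batch, (len(batches), p))
    b_plate = rng.normal(0.0, config.sd_plate, (len(plates), p))
    b_edge = rng.normal(0.0, config.sd_edge, (len(plates), p))
    b_div = rng.normal(0.0, config.sd_div, (len(divs), p))
    b_shrna = rng.normal(0.0, config.sd_shrna, (len(shrna_list), p))

    efficacy = rng.uniform(*config.efficacy_range, len(shrna_list))
    duds = rng.random(len(shrna_list)) < config.dud_fraction
    efficacy[duds] = 0.0
    efficacy_map = dict(zip(shrna_list, efficacy))

    corr = _residual_correlation(config)
    chol = np.linalg.cholesky(corr)
    resid = rng.standard_normal((len(layout), p)) @ chol.T * config.sd_residual

    bi = layout["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    pi = layout["plate"].map({q: i for i, q in enumerate(plates)}).to_numpy()
    di = layout["div"].map({d: i for i, d in enumerate(divs)}).to_numpy()
    edge = layout["is_edge"].to_numpy()

    x = resid
    x += b_batch[bi] + b_plate[pi] + b_div[di]
    x[edge] += b_edge[pi[edge]]

    si = np.array(
        [shrna_list.index(s) if s in shrna_gene else -1
         for s in layout["shrna_id"]]
    )
    has_shrna = si >= 0
    x[has_shrna] += b_shrna[si[has_shrna]]

    # Planted gene effects, scaled by per-shRNA efficacy.
    eff = np.zeros((len(layout), p))
    for j, param in enumerate(PARAMETERS):
        if config.div_trend and param in _DIV_TREND:
            x[:, j] += _DIV_TREND[param] * di
        for (shrna, div_idx), rows in layout.groupby(
            [layout["shrna_id"], di]
        ).groups.items():
            gene = shrna_gene.get(shrna)
            if not gene:
                continue
            label = config.gene_archetypes.get(gene, "0")
            arch = config.archetypes[label]
            e = arch.effect(param, int(div_idx), len(divs))
            if e:
                eff[layout.index.get_indexer(rows), j] = (
                    e * efficacy_map[shrna]
                )
    x += eff

    values = np.empty_like(x)
    for j, param in enumerate(PARAMETERS):
        values[:, j] = config.baselines[param] * np.exp2(x[:, j])

    out = layout.drop(columns=["replicate"]).copy()
    for j, param in enumerate(PARAMETERS):
        out[param] = values[:, j]
    return out


def planted_effect_genes(config: SimulationConfig) -> dict[str, str]:
    """Genes planted with a non-null archetype (gene -> archetype label)."""
    present = set(config.design.genes) | {config.design.positive_control_label}
    return {
        g: a for g, a in config.gene_archetypes.items()
        if a != "0" and g in present
    }


# ---------------------------------------------------------------------------
# Proteomics generator
# ---------------------------------------------------------------------------

class ProteomicsTables(NamedTuple):
    """Protein x sample intensities, sample metadata, and per-id q-values."""

    quant: pd.DataFrame      # index protein id, 'description' + sample columns
    metadata: pd.DataFrame   # sample, group, replicate, median_q
    q_values: pd.DataFrame   # same shape/columns as quant samples


_CONTAMINANT_TEMPLATES = (
    ("KRT{i}_SYN", "Keratin, type I cytoskeletal {i} (synthetic contaminant)"),
    ("IGH{i}_SYN", "Immunoglobulin heavy chain {i} (synthetic contaminant)"),
    ("TRY{i}_SYN", "Trypsin isoform {i} (synthetic contaminant)"),
)


@dataclass(frozen=True)
class SyntheticProteomicsConfig:
    """One knockdown proteomics experiment: all shRNAs of one or more genes
    quantified against a shared scrambled-control group."""

    n_proteins: int = 2500
    replicates_per_group: int = 3
    #: gene -> shRNA group labels sharing this experiment's scrambled group.
    genes: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"Tcf4": [f"Tcf4_sh{i}" for i in (1, 2, 3, 4)]}
    )
    #: gene -> {protein id -> signed log2 effect} planted concordantly in
    #: every shRNA group of that gene.
    planted_regulated: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    #: Per-shRNA multiplicative jitter range applied to planted effects
    #: (sign is never flipped, keeping effects concordant).
    effect_jitter: tuple[float, float] = (0.7, 1.3)
    noise_sd: float = 0.25
    contaminant_fraction: float = 0.02
    #: Per-identification q-values: confident identifications sit at the
    #: reporting floor ``q_bulk_scale`` (as search engines floor q-values),
    #: a ``q_tail_fraction`` of dubious identifications is drawn from a
    #: broad tail above any sensible cutoff.
    q_bulk_scale: float = 1e-4
    q_tail_fraction: float = 0.05
    missing_rate: float = 0.0
    #: group label -> replicate index whose median q is inflated 50x
    #: (planted outlier replicates).
    planted_outliers: Mapping[str, int] = field(default_factory=dict)
    scrambled_group: str = "scrambled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ScreenConfigError("replicates_per_group must be >= 2")
        if not (0 <= self.contaminant_fraction <= 1):
            raise ScreenConfigError("contaminant_fraction must lie in [0, 1]")
        planted = {
            pid for effs in self.planted_regulated.values() for pid in effs
        }
        n_named = len(planted)
        if n_named > self.n_proteins:
            raise ScreenConfigError("more planted proteins than n_proteins")


def generate_proteomics(config: SyntheticProteomicsConfig) -> ProteomicsTables:
    """Simulate a protein quantification experiment with planted regulation."""
    rng = np.random.default_rng(config.seed)
    r = config.replicates_per_group

    planted_ids = sorted({
        pid for effs in config.planted_regulated.values() for pid in effs
    })
    n_contam = int(round(config.contaminant_fraction * config.n_proteins))
    n_background = config.n_proteins - len(planted_ids) - n_contam
    if n_background < 0:
        raise ScreenConfigError(
            "n_proteins too small for planted + contaminant rows"
        )
    background_ids = [f"PROT{i:05d}" for i in range(1, n_background + 1)]
    contam_rows = []
    for i in range(n_contam):
        tpl_id, tpl_desc = _CONTAMINANT_TEMPLATES[i % 3]
        contam_rows.append(
            (tpl_id.format(i=i + 1), tpl_desc.format(i=i + 1))
        )
    proteins = (
        [(pid, f"planted regulated protein {pid} (synthetic)")
         for pid in planted_ids]
        + [(pid, f"background protein {pid} (synthetic)")
           for pid in background_ids]
        + contam_rows
    )

    groups = [config.scrambled_group] + [
        s for sids in config.genes.values() for s in sids
    ]
    samples = [f"{g}_r{i + 1}" for g in groups for i in range(r)]
    meta = pd.DataFrame({
        "sample": samples,
        "group": [g for g in groups for _ in range(r)],
        "replicate": [i + 1 for _ in groups for i in range(r)],
    })

    shrna_gene = {s: g for g, sids in config.genes.items() for s in sids}
    n = len(proteins)
    base = rng.uniform(10.0, 20.0, n)  # log2 abundance baselines
    log2 = np.tile(base[:, None], (1, len(samples)))
    if config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, log2.shape)

    pid_index = {pid: i for i, (pid, _) in enumerate(proteins)}
    for ci, sample in enumerate(samples):
        group = meta.loc[ci, "group"]
        gene = shrna_gene.get(group)
        if gene is None:
            continue
        effects = config.planted_regulated.get(gene, {})
        if not effects:
            continue
        jitter = _shrna_jitter(config, gene, group)
        for pid, eff in effects.items():
            log2[pid_index[pid], ci] += eff * jitter

    intensity = np.exp2(log2)
    if config.missing_rate > 0:
        mask = rng.random(intensity.shape) < config.missing_rate
        intensity[mask] = np.nan

    # Per-identification q-values: a confident bulk at the reporting floor
    # plus a broad dubious tail; planted outlier replicates are inflated 50x.
    q = np.full(intensity.shape, config.q_bulk_scale)
    tail = rng.random(intensity.shape) < config.q_tail_fraction
    q[tail] = rng.uniform(0.01, 0.5, tail.sum())
    for group, rep_idx in config.planted_outliers.items():
        col = samples.index(f"{group}_r{rep_idx + 1}")
        q[:, col] *= 50.0

    quant = pd.DataFrame(
        intensity, index=[pid for pid, _ in proteins], columns=samples
    )
    quant.insert(0, "description", [desc for _, desc in proteins])
    quant.index.name = "protein_id"
    qdf = pd.DataFrame(q, index=quant.index, columns=samples)
    meta["median_q"] = [float(np.nanmedian(q[:, i])) for i in range(len(samples))]
    return ProteomicsTables(quant, meta, qdf)


def _shrna_jitter(
    config: SyntheticProteomicsConfig, gene: str, group: str
) -> float:
    """Deterministic per-shRNA positive effect multiplier (sign-preserving)."""
    h = zlib.crc32(f"{config.seed}|{gene}|{group}".encode()) % (2**31)
    lo, hi = config.effect_jitter
    return lo + (hi - lo) * np.random.default_rng(h).random()


def make_worked_example_configs(
    seed: int = 0,
    set_sizes: Mapping[str, int] | None = None,
) -> dict[str, SyntheticProteomicsConfig]:
    """Noise-free knockdown experiments with planted regulated sets.

    Builds one experiment per gene with planted regulated-protein sets of
    the configured sizes (defaults: Tcf4 94, Tbr1 61, Top3b 67), pairwise
    overlaps of 2-4 proteins and exactly one protein shared by all three —
    the set structure reported for the original knockdown screens. With
    ``noise_sd = 0`` the filter chain's output is determined purely by its
    filtering logic: unregulated proteins have exactly zero fold change
    (which the concordance rule counts as discordant), so this fixture
    audits the rules, not sampling noise. Contaminant rows and a planted
    outlier replicate are included so every filter stage does real work.
    """
    sizes = dict(set_sizes or {"Tcf4": 94, "Tbr1": 61, "Top3b": 67})
    genes = list(sizes)
    rng = np.random.default_rng(seed)

    shared_all = ["SHARED_ALL_1"]
    pair_overlap = {
        (genes[0], genes[1]): [f"SHARED_{genes[0]}_{genes[1]}_{i}" for i in (1, 2)],
        (genes[0], genes[2]): [f"SHARED_{genes[0]}_{genes[2]}_{i}" for i in (1, 2, 3)],
        (genes[1], genes[2]): [f"SHARED_{genes[1]}_{genes[2]}_1"],
    }
    members: dict[str, list[str]] = {g: list(shared_all) for g in genes}
    for (a, b), ids in pair_overlap.items():
        members[a] += ids
        members[b] += ids
    for g in genes:
        n_private = sizes[g] - len(members[g])
        members[g] += [f"REG_{g}_{i:03d}" for i in range(1, n_private + 1)]

    shrnas = {
        genes[0]: [f"{genes[0]}_sh{i}" for i in (1, 3, 4, 5)],
        genes[1]: [f"{genes[1]}_sh{i}" for i in (2, 3, 4)],
        genes[2]: [f"{genes[2]}_sh{i}" for i in (1, 2, 3)],
    }
    configs = {}
    for g in genes:
        effects = {}
        for pid in members[g]:
            magnitude = float(rng.uniform(0.5, 1.5))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[pid] = sign * magnitude
        configs[g] = SyntheticProteomicsConfig(
            n_proteins=2200 + int(rng.integers(0, 400)),
            genes={g: shrnas[g]},
            planted_regulated={g: effects},
            noise_sd=0.0,
            contaminant_fraction=0.02,
            q_tail_fraction=0.02,
            planted_outliers={shrnas[g][0]: 2} if g == genes[1] else {},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return configs


# ---------------------------------------------------------------------------
# Network / annotation generator
# ---------------------------------------------------------------------------

def generate_network_and_annotations(
    n_nodes: int,
    edge_density: float,
    planted_module: Sequence[str],
    seed: int = 0,
    n_random_sets: int = 10,
    module_score_range: tuple[float, float] = (0.8, 0.99),
    background_score_range: tuple[float, float] = (0.15, 0.95),
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """A weighted edge list with a planted fully connected module, plus
    GMT-style annotation sets (one of which equals the planted module).

    Background node pairs outside the module are connected independently
    with probability ``edge_density``; module-internal pairs are always
    connected with high confidence scores.
    """
    if not (0.0 <= edge_density <= 1.0):
        raise ScreenConfigError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    module = sorted(set(planted_module))
    if len(module) > n_nodes:
        raise ScreenConfigError("planted module larger than n_nodes")
    n_background = n_nodes - len(module)
    nodes = module + [f"NODE{i:05d}" for i in range(1, n_background + 1)]
    module_set = set(module)

    edges: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(module, 2):
        edges.append((a, b, float(rng.uniform(*module_score_range))))
    if edge_density > 0:
        for a, b in itertools.combinations(nodes, 2):
            if a in module_set and b in module_set:
                continue
            if rng.random() < edge_density:
                edges.append(
                    (a, b, float(rng.uniform(*background_score_range)))
                )
    network = pd.DataFrame(edges, columns=["node_a", "node_b", "combined_score"])

    annotations: dict[str, set[str]] = {}
    if module:
        annotations["MF:planted_module"] = set(module)
    for i in range(n_random_sets):
        size = int(rng.integers(5, max(6, n_nodes // 10)))
        annotations[f"MF:random_set_{i + 1}"] = set(
            rng.choice(nodes, size=min(size, n_nodes), replace=False)
        )
    return network, annotations


def null_screen_config(seed: int, **overrides) -> SimulationConfig:
    """A screen with every gene planted null (for calibration studies)."""
    cfg = SimulationConfig(
        gene_archetypes={},
        dud_fraction=0.0,
        seed=seed,
        **overrides,
    )
    return cfg


def replace_config(cfg: SimulationConfig, **kw) -> SimulationConfig:
    return replace(cfg, **kw)
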