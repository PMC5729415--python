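"""Ground-truth simulators for every input the package consumes.

The generators emulate the study conditions of a two-species mitochondrial
microarray experiment: ortholog gene pairs with planted substitutions and
C-to-U editing sites, complete annotated two-genome fixtures (plus- and
minus-strand genes, a spliced gene, tRNA/rRNA genes, species-unique
genes), spotted slides with spike-in calibration spots under a
multiplicative-lognormal + additive-background + detector-ceiling noise
model, ten-fraction gradient profiles with a puromycin counterpart, and
qPCR CT tables.  Every generator is a pure function of its configuration
and seed: repeated calls are byte-identical, and each returns the truth
needed for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from mitochip.genome_io import (
    EditingSite,
    GeneFeature,
    GenomeRecord,
    OrthologPair,
    reverse_complement,
)
from mitochip.polysome_qpcr import GradientProfile, N_FRACTIONS

BASES = np.array(list("ACGT"))


def _default_spikes() -> tuple[float, ...]:
    # five points per decade across 1 pg .. 10 ng, mirroring a commercial
    # spike-in control series
    return tuple(float(x) for x in np.geomspace(1.0, 10_000.0, 21))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for all simulators.

    Sequence side: ~900-nt genes at 45% GC (plant mitochondrial coding
    regions), ~1% cross-species substitution rate, ~15 C-to-U editing
    sites per gene.  Slide side: signal = clip(slope·abundance·LN(σ) +
    background, 0, ceiling) with a 16-bit detector, six replicate blocks
    per slide, and a 1 pg–10 ng spike series.  Gradient side: bound/free
    loading ratio 3 with near-complete (d = 0.9) puromycin dissociation.
    """

    seed: int = 0
    n_genes: int = 30
    gene_length: int = 900
    gc: float = 0.45
    mismatch_rate: float = 0.01
    editing_sites_per_gene: int = 15
    noise_sigma: float = 0.1
    bg_mean: float = 50.0
    bg_sd: float = 5.0
    detector_max: float = 65535.0
    slope_true: float = 50.0
    spike_amounts: tuple[float, ...] = field(default_factory=_default_spikes)
    n_blocks: int = 6
    loading_ratio: float = 3.0
    puromycin_dissociation: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")
        if not (0.0 <= self.mismatch_rate <= 1.0):
            raise ValueError("mismatch_rate must be in [0, 1]")
        if not (0.0 <= self.puromycin_dissociation <= 1.0):
            raise ValueError("puromycin_dissociation must be in [0, 1]")
        if self.detector_max <= 0 or self.slope_true <= 0:
            raise ValueError("detector_max and slope_true must be positive")


# ---------------------------------------------------------------------------
# sequences

def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


@dataclass(frozen=True)
class OrthologTruth:
    mismatch_positions: tuple[int, ...]
    editing_sites: tuple[EditingSite, ...]


def gen_ortholog_pair(
    cfg: SimConfig | None = None,
    seed: int | None = None,
    gene: str = "gene1",
    length: int | None = None,
    mismatch_positions: Sequence[int] | None = None,
    n_mismatches: int | None = None,
    n_editing_sites: int = 0,
) -> tuple[OrthologPair, OrthologTruth]:
    """One ortholog pair with planted substitutions and editing sites.

    The species-B sequence is sampled at the configured GC; species A is
    derived by substituting at the given (or sampled) positions.  Editing
    sites are planted at C positions of the species-B sequence and left
    unapplied, so the returned ``seq_b`` is the *unedited* sequence when
    ``n_editing_sites > 0`` (callers apply the sites themselves).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    length = length or cfg.gene_length
    seq_b = random_sequence(rng, length, cfg.gc)

    if mismatch_positions is None:
        if n_mismatches is None:
            n_mismatches = int(rng.binomial(length, cfg.mismatch_rate))
        if n_mismatches > length:
            raise ValueError("more planted mismatches than positions")
        mismatch_positions = sorted(
            int(i) for i in rng.choice(length, size=n_mismatches, replace=False)
        )
    else:
        mismatch_positions = sorted(int(i) for i in mismatch_positions)
        if len(set(mismatch_positions)) != len(mismatch_positions):
            raise ValueError("duplicate mismatch positions")
        if mismatch_positions and mismatch_positions[-1] >= length:
            raise ValueError("mismatch position outside gene")

    seq_a = list(seq_b)
    for pos in mismatch_positions:
        seq_a[pos] = _substitute(rng, seq_a[pos])

    c_positions = [i for i, b in enumerate(seq_b) if b == "C"]
    if n_editing_sites > len(c_positions):
        raise ValueError("not enough C positions for requested editing sites")
    sites = tuple(
        EditingSite(gene=gene, cds_position=int(p))
        for p in sorted(
            rng.choice(c_positions, size=n_editing_sites, replace=False)
        )
    ) if n_editing_sites else ()

    pair = OrthologPair(
        gene=gene, seq_a="".join(seq_a), seq_b=seq_b, category="protein"
    )
    return pair, OrthologTruth(
        mismatch_positions=tuple(mismatch_positions), editing_sites=sites
    )


def _dense_mismatch_positions(length: int, window: int = 68, budget: int = 3
                              ) -> list[int]:
    """Positions spaced so every ``window``-nt stretch holds > ``budget``
    mismatches — makes a shared probe infeasible by construction."""
    spacing = window // (budget + 1)  # 17 for the 68/3 defaults
    return list(range(0, length, spacing))


@dataclass
class GenomePairTruth:
    """Per-gene construction record of a synthetic genome pair."""

    genes: dict[str, dict] = field(default_factory=dict)

    def expected_counts(self) -> dict[str, int]:
        shared = sum(1 for g in self.genes.values() if g["expect"] == "shared")
        spec_genes = [g for g in self.genes.values() if g["expect"] != "shared"]
        n_specific_probes = sum(
            2 if g["expect"] == "specific_both" else 1 for g in spec_genes
        )
        return {
            "n_probes": shared + n_specific_probes,
            "n_shared_genes": shared,
            "n_specific_genes": len(spec_genes),
        }


def gen_genome_pair(
    cfg: SimConfig | None = None,
    seed: int | None = None,
    n_shared: int = 5,
    n_divergent: int = 1,
    n_unique_a: int = 1,
    n_unique_b: int = 1,
    n_editing_genes: int = 1,
    spacer: int = 120,
) -> tuple[GenomeRecord, GenomeRecord, dict[str, list[EditingSite]], GenomePairTruth]:
    """Two annotated genomes with a controlled ortholog structure.

    ``n_shared`` conserved genes (0–3 planted substitutions each, so a
    shared probe is feasible), ``n_divergent`` genes with substitutions
    dense enough that no shared window exists, and species-unique genes on
    each side.  The shared set includes one minus-strand gene, one
    two-exon gene, one tRNA and one rRNA.  The first ``n_editing_genes``
    shared genes carry a species-B editing table (genomes hold the
    unedited C).  Returns (record A, record B, editing table B, truth).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = GenomePairTruth()
    editing_b: dict[str, list[EditingSite]] = {}

    # (name, category, present, expect, layout)
    plan: list[dict] = []
    shared_names = ["cox1", "atp9", "nad4", "cob", "rps3", "atp6", "ccmC",
                    "nad7", "matR", "cox3"][:n_shared]
    for i, name in enumerate(shared_names):
        layout = "plus"
        category = "protein"
        if i == 1 and n_shared >= 2:
            layout = "minus"
        elif i == 2 and n_shared >= 3:
            layout = "two_exon"
        if i == 3 and n_shared >= 4:
            category, name = "tRNA", "trnM"
        elif i == 4 and n_shared >= 5:
            category, name = "rRNA", "rrn18"
        plan.append(
            dict(name=name, category=category, present="both",
                 expect="shared", layout=layout)
        )
    for i in range(n_divergent):
        plan.append(
            dict(name=f"orf{200 + i}", category="orf", present="both",
                 expect="specific_both", layout="plus")
        )
    for i in range(n_unique_a):
        plan.append(
            dict(name=f"orf{300 + i}", category="orf", present="A",
                 expect="specific_A", layout="plus")
        )
    for i in range(n_unique_b):
        plan.append(
            dict(name=f"orf{400 + i}", category="orf", present="B",
                 expect="specific_B", layout="plus")
        )

    parts_a: list[str] = []
    parts_b: list[str] = []
    feats_a: list[GeneFeature] = []
    feats_b: list[GeneFeature] = []
    pos_a = pos_b = 0
    n_edited = 0

    def _emit(parts, feats, pos, sense_seq, name, category, layout, rng):
        """Append one gene locus; returns the new genome cursor."""
        parts.append(random_sequence(rng, spacer, 0.4))
        pos += spacer
        if layout == "two_exon":
            exon1 = sense_seq[: len(sense_seq) // 2]
            exon2 = sense_seq[len(sense_seq) // 2 :]
            intron = random_sequence(rng, 90, 0.35)
            parts.extend([exon1, intron, exon2])
            intervals = (
                (pos, pos + len(exon1)),
                (pos + len(exon1) + len(intron),
                 pos + len(exon1) + len(intron) + len(exon2)),
            )
            pos = intervals[1][1]
            strand = "+"
        elif layout == "minus":
            locus = reverse_complement(sense_seq)
            parts.append(locus)
            intervals = ((pos, pos + len(locus)),)
            pos += len(locus)
            strand = "-"
        else:
            parts.append(sense_seq)
            intervals = ((pos, pos + len(sense_seq)),)
            pos += len(sense_seq)
            strand = "+"
        feats.append(
            GeneFeature(name=name, category=category, strand=strand,
                        intervals=intervals)
        )
        return pos

    for entry in plan:
        length = 75 if entry["category"] == "tRNA" else cfg.gene_length
        gene_seed = int(rng.integers(2**31))
        if entry["expect"] == "shared":
            n_mm = int(rng.integers(0, 4))
            n_ed = 0
            if (entry["category"] == "protein"
                    and n_edited < n_editing_genes):
                n_ed = min(cfg.editing_sites_per_gene, 5)
                n_edited += 1
            pair, ptruth = gen_ortholog_pair(
                cfg, seed=gene_seed, gene=entry["name"], length=length,
                n_mismatches=n_mm, n_editing_sites=n_ed,
            )
            if ptruth.editing_sites:
                editing_b[entry["name"]] = list(ptruth.editing_sites)
            seq_a, seq_b = pair.seq_a, pair.seq_b
        elif entry["expect"] == "specific_both":
            positions = _dense_mismatch_positions(length)
            pair, ptruth = gen_ortholog_pair(
                cfg, seed=gene_seed, gene=entry["name"], length=length,
                mismatch_positions=positions,
            )
            seq_a, seq_b = pair.seq_a, pair.seq_b
        else:
            seq = random_sequence(
                np.random.default_rng(gene_seed), length, cfg.gc
            )
            seq_a = seq_b = seq
            ptruth = OrthologTruth((), ())

        if entry["present"] in ("both", "A"):
            pos_a = _emit(parts_a, feats_a, pos_a, seq_a, entry["name"],
                          entry["category"], entry["layout"], rng)
        if entry["present"] in ("both", "B"):
            pos_b = _emit(parts_b, feats_b, pos_b, seq_b, entry["name"],
                          entry["category"], entry["layout"], rng)
        truth.genes[entry["name"]] = {
            "category": entry["category"], "present": entry["present"],
            "expect": entry["expect"],
            "mismatch_positions": ptruth.mismatch_positions,
            "editing_sites": ptruth.editing_sites,
        }

    parts_a.append(random_sequence(rng, spacer, 0.4))
    parts_b.append(random_sequence(rng, spacer, 0.4))
    rec_a = GenomeRecord(
        accession="SYNA01", sequence="".join(parts_a), features=tuple(feats_a)
    )
    rec_b = GenomeRecord(
        accession="SYNB01", sequence="".join(parts_b), features=tuple(feats_b)
    )
    return rec_a, rec_b, editing_b, truth


_FEATURE_TYPE = {"protein": "CDS", "orf": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Serialize a GenomeRecord as a GenBank flat file (round-trips through
    :func:`mitochip.genome_io.read_genbank`)."""
    seq_record = SeqRecord(
        Seq(record.sequence), id=record.accession, name=record.accession[:16],
        description="synthetic organelle genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for feat in record.features:
        strand = 1 if feat.strand == "+" else -1
        locs = [
            SimpleLocation(start, end, strand) for start, end in feat.intervals
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(
            locs if strand == 1 else locs[::-1]
        )
        seq_record.features.append(
            SeqFeature(
                location, type=_FEATURE_TYPE[feat.category],
                qualifiers={"gene": [feat.name]},
            )
        )
    SeqIO.write(seq_record, str(path), "genbank")


def gen_decoys(
    rng: np.random.Generator, n: int = 3, length: int = 10_000, gc: float = 0.38
) -> dict[str, str]:
    """Random decoy sequences (plastid-genome stand-ins)."""
    return {
        f"decoy{i + 1}": random_sequence(rng, length, gc) for i in range(n)
    }


# ---------------------------------------------------------------------------
# slides

def gen_slide(
    slide_id: str,
    true_abundances: Mapping[str, float],
    cfg: SimConfig | None = None,
    seed: int | None = None,
    n_negative: int = 4,
) -> pd.DataFrame:
    """One slide's spot table from per-probe truth abundances (pg).

    Signal model per spot: fg = clip(slope·abundance·LN(σ) + bg, 0,
    ceiling) with the local background drawn per spot; calibration spots
    are generated from the spike series under the same model, and the
    whole layout is repeated over the configured replicate blocks.
    In the noise-free limit (σ = 0, bg_sd = 0, no clipping) the
    quantification pipeline recovers the truth exactly.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for block in range(1, cfg.n_blocks + 1):
        for probe_id, abundance in true_abundances.items():
            if abundance < 0:
                raise ValueError(f"negative truth abundance for {probe_id}")
            rows.append(("gene", probe_id, abundance, np.nan))
        for i, amount in enumerate(cfg.spike_amounts):
            rows.append(("calibration", f"spike{i + 1:02d}", amount, amount))
        for i in range(n_negative):
            rows.append(("negative", f"neg{i + 1}", 0.0, np.nan))

    n = len(rows)
    bg = np.maximum(rng.normal(cfg.bg_mean, cfg.bg_sd, size=n), 0.0)
    noise = (
        np.exp(rng.normal(0.0, cfg.noise_sigma, size=n))
        if cfg.noise_sigma > 0 else np.ones(n)
    )
    amounts = np.array([r[2] for r in rows])
    fg = np.clip(cfg.slope_true * amounts * noise + bg, 0.0, cfg.detector_max)

    block_col = np.repeat(
        np.arange(1, cfg.n_blocks + 1), n // cfg.n_blocks
    )
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "block": block_col,
            "probe_id": [r[1] for r in rows],
            "spot_class": [r[0] for r in rows],
            "fg_mean": fg,
            "bg_local": bg,
            "known_amount_pg": [r[3] for r in rows],
        }
    )


#: replicate structure of the tissue panel (biological replicates per organ)
DEFAULT_REPLICATES: dict[str, int] = {
    "young_leaves": 4,
    "expanded_leaves": 4,
    "roots": 3,
    "flowers": 3,
    "floral_buds": 2,
}


def gen_true_abundances(
    genes: Sequence[str],
    tissues: Sequence[str],
    seed: int = 0,
    base_median_pg: float = 50.0,
    gene_sigma: float = 1.0,
    tissue_effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-tissue truth abundances (pg-equivalents per slide input).

    Gene baselines are lognormal around ``base_median_pg``; tissue effects
    are multiplicative fold changes (1.0 everywhere = null).
    """
    rng = np.random.default_rng(seed)
    base = base_median_pg * np.exp(rng.normal(0.0, gene_sigma, len(genes)))
    data = {
        t: base * (tissue_effects.get(t, 1.0) if tissue_effects else 1.0)
        for t in tissues
    }
    return pd.DataFrame(data, index=list(genes))


def gen_experiment(
    truth: pd.DataFrame,
    replicates: Mapping[str, int] | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    fraction: str = "total",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spot tables plus slide-design table for a replicated tissue panel.

    ``truth`` is a gene × tissue abundance matrix; each tissue gets the
    configured number of replicate slides.  Returns (spots, design).
    """
    cfg = cfg or SimConfig()
    replicates = dict(replicates or DEFAULT_REPLICATES)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spot_frames, design_rows = [], []
    for tissue in truth.columns:
        if tissue not in replicates:
            raise KeyError(f"no replicate count for tissue {tissue!r}")
        for rep in range(1, replicates[tissue] + 1):
            slide_id = f"{tissue}_{fraction}_r{rep}"
            slide_seed = int(rng.integers(2**31))
            spot_frames.append(
                gen_slide(slide_id, truth[tissue].to_dict(), cfg,
                          seed=slide_seed)
            )
            design_rows.append(
                {"slide_id": slide_id, "tissue": tissue,
                 "fraction": fraction, "replicate": rep}
            )
    return (
        pd.concat(spot_frames, ignore_index=True),
        pd.DataFrame(design_rows),
    )


# ---------------------------------------------------------------------------
# gradients and qPCR

def gen_gradient_profiles(
    ratios: Mapping[tuple[str, str], float],
    cfg: SimConfig | None = None,
    seed: int | None = None,
    total_mass: float = 1000.0,
    jitter_alpha: float = 200.0,
    with_puromycin: bool = True,
) -> tuple[list[GradientProfile], dict[tuple[str, str], float]]:
    """Ten-fraction profiles with known bound/free loading ratios.

    For each (gene, tissue) with truth ratio r, a fraction r/(1+r) of the
    total mass is spread over fractions 6–10 and the rest over 1–5, each
    with Dirichlet jitter (larger ``jitter_alpha`` = less jitter).  The
    puromycin counterpart moves a fraction d of the bound mass into the
    light fractions, d being the configured dissociation.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    profiles: list[GradientProfile] = []
    truth: dict[tuple[str, str], float] = {}
    for (gene, tissue), ratio in sorted(ratios.items()):
        if ratio < 0:
            raise ValueError("loading_ratio truth must be non-negative")
        bound = total_mass * ratio / (1.0 + ratio)
        free = total_mass - bound
        w_free = rng.dirichlet([jitter_alpha] * 5)
        w_bound = rng.dirichlet([jitter_alpha] * 5)
        intens = np.concatenate([free * w_free, bound * w_bound])
        profiles.append(
            GradientProfile(
                gene=gene, tissue=tissue,
                intensities=tuple(float(x) for x in intens),
            )
        )
        truth[(gene, tissue)] = ratio
        if with_puromycin:
            d = cfg.puromycin_dissociation
            moved = d * bound
            w_free_p = rng.dirichlet([jitter_alpha] * 5)
            w_bound_p = rng.dirichlet([jitter_alpha] * 5)
            intens_p = np.concatenate(
                [(free + moved) * w_free_p, (bound - moved) * w_bound_p]
            )
            profiles.append(
                GradientProfile(
                    gene=gene, tissue=tissue,
                    intensities=tuple(float(x) for x in intens_p),
                    treatment="puromycin",
                )
            )
    return profiles, truth


def profiles_to_frame(profiles: Sequence[GradientProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"gene": p.gene, "tissue": p.tissue, "treatment": p.treatment}
        row.update({f"f{i + 1}": p.intensities[i] for i in range(N_FRACTIONS)})
        rows.append(row)
    return pd.DataFrame(rows)


def gen_ct_table(
    samples: Sequence[str],
    mito_copies: float = 50.0,
    nuclear_copies: float = 1.0,
    target_levels: Mapping[str, float] | None = None,
    reference_targets: Sequence[str] = ("EF1a", "GAPDH"),
    reference_level: float = 100.0,
    ct_at_unit: float = 32.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT table under a perfect-efficiency model: ct = ct_at_unit − log2(level).

    Doubling a template level lowers its CT by exactly one cycle, so
    simulated copy-number changes map one-to-one onto ΔCT shifts.
    """
    rng = np.random.default_rng(seed)
    target_levels = dict(target_levels or {"RpoTm": 20.0, "RpoTmp": 5.0})

    def _ct(level: float) -> float:
        if level <= 0:
            raise ValueError("template level must be positive")
        return ct_at_unit - math.log2(level) + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )

    rows = []
    for sample in samples:
        rows.append(
            {"sample": sample, "target": "mito_region", "role": "mito_region",
             "ct": _ct(mito_copies)}
        )
        rows.append(
            {"sample": sample, "target": "nuclear_region",
             "role": "nuclear_region", "ct": _ct(nuclear_copies)}
        )
        for ref in reference_targets:
            rows.append(
                {"sample": sample, "target": ref, "role": "reference",
                 "ct": _ct(reference_level)}
            )
        for target, level in target_levels.items():
            rows.append(
                {"sample": sample, "target": target, "role": "target",
                 "ct": _ct(level)}
            )
    return pd.DataFrame(rows)
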