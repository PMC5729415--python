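"""Cross-species oligonucleotide probe design.

One probe per gene is sought that hybridizes to the orthologous transcript
of both species: length 68–71 nt, GC content near 50%, and at most three
cross-species mismatches, placed as close to the oligo ends as possible
(central mismatches destabilize the duplex most).  Where no window of the
ortholog alignment satisfies all constraints, two species-specific probes
are designed instead, each optimized for GC content alone.

The literature gives constraints rather than an objective; this module
concretizes them as a composite score,

    score = w_gc * |GC_B - gc_target| + w_pos * sum_i centrality(p_i, L)

with ``centrality(p, L) = 1 - 2*|p/(L-1) - 1/2|`` (0 at either end, 1 at
the center), minimized over every gapless alignment window of every
allowed length.  Shared probes always carry the species-B (Arabidopsis
role) sequence.  Probes are sense-strand because the labeled target is
first-strand cDNA, which is antisense to the mRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from mitochip.genome_io import (
    GenomeRecord,
    OrthologPair,
    PairingResult,
    QUANTIFIABLE_CATEGORIES,
    UnpairedGene,
    pair_orthologs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConstraints:
    """Probe-design constraints and scoring weights.

    ``min_len``/``max_len`` bound the oligo length in nucleotides,
    ``gc_target`` is the desired GC fraction, ``max_mismatches`` the
    cross-species mismatch budget for a shared probe, and the two weights
    balance GC deviation against mismatch-position penalties in the score.
    """

    min_len: int = 68
    max_len: int = 71
    gc_target: float = 0.5
    max_mismatches: int = 3
    weight_gc: float = 1.0
    weight_pos: float = 1.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.weight_gc < 0 or self.weight_pos < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class CandidateWindow:
    """A gapless alignment window considered for a shared probe."""

    gene: str
    offset_a: int
    offset_b: int
    length: int
    seq_a: str
    seq_b: str
    mismatch_positions: tuple[int, ...]
    gc_b: float
    feasible: bool
    infeasible_reason: str | None = None
    score: float | None = None


@dataclass(frozen=True)
class ProbeRecord:
    """A designed oligonucleotide.

    ``scope`` is ``shared`` (one oligo serving both species, species-B
    sequence), ``specific_A`` or ``specific_B``.  ``quantifiable`` is False
    for tRNA/rRNA probes, which are printed but excluded from abundance
    estimation downstream.
    """

    probe_id: str
    genes: tuple[str, ...]
    scope: str
    sequence: str
    source_species: str
    gc: float
    mismatches_vs_other_species: int | None
    design_score: float
    quantifiable: bool = True

    def __post_init__(self) -> None:
        if self.scope not in ("shared", "specific_A", "specific_B"):
            raise ValueError(f"bad scope {self.scope!r}")
        if self.scope == "shared" and self.source_species != "B":
            raise ValueError("shared probes must carry the species-B sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DesignDecision:
    """Per-gene entry of the design report."""

    gene: str
    category: str
    n_feasible_windows: int
    decision: str  # shared | specific_both | specific_A | specific_B | none
    reason: str
    chosen_offset_b: int | None = None
    chosen_length: int | None = None
    chosen_mismatches: int | None = None
    chosen_score: float | None = None


@dataclass
class ProbeSet:
    probes: list[ProbeRecord] = field(default_factory=list)
    design_report: list[DesignDecision] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        """Headline counts: total oligos, shared-probe genes, separate-probe genes."""
        shared_genes = {p.genes[0] for p in self.probes if p.scope == "shared"}
        specific_genes = {
            p.genes[0] for p in self.probes if p.scope != "shared"
        }
        return {
            "n_probes": len(self.probes),
            "n_shared_genes": len(shared_genes),
            "n_specific_genes": len(specific_genes),
        }


def gc_fraction(seq: str) -> float:
    """GC fraction of an unambiguous DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT letters: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def centrality_penalty(position: int, length: int) -> float:
    """Destabilization weight of a mismatch at ``position`` in an oligo.

    0 at either end, 1 at the exact center; linear in between.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if position < 0 or position >= length:
        raise ValueError(f"position {position} outside [0, {length})")
    return 1.0 - 2.0 * abs(position / (length - 1) - 0.5)


def score_window(window: CandidateWindow, c: DesignConstraints) -> float:
    """Composite design score of a feasible window (lower is better)."""
    if not window.feasible:
        raise ValueError(
            f"window at b-offset {window.offset_b} is infeasible "
            f"({window.infeasible_reason}); it must not be scored"
        )
    penalty = sum(
        centrality_penalty(p, window.length) for p in window.mismatch_positions
    )
    return c.weight_gc * abs(window.gc_b - c.gc_target) + c.weight_pos * penalty


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise alignment, returned as two equal-length gapped strings.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1.  The high
    gap-open cost reflects that indel-tolerant probes are not designed: any
    gap renders the surrounding windows infeasible, so alignments should
    prefer substitutions.  Biopython's first-reported optimal alignment is
    taken, which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def enumerate_windows(
    alignment: tuple[str, str],
    c: DesignConstraints,
    gene: str = "",
    boundaries_a: frozenset[int] | Iterable[int] = frozenset(),
    boundaries_b: frozenset[int] | Iterable[int] = frozenset(),
) -> list[CandidateWindow]:
    """All alignment windows of each allowed length, with feasibility flags.

    A window is feasible when it contains no gap column, no N, at most
    ``c.max_mismatches`` mismatching columns, and does not span a splice
    junction of either species (probes must sit within one exon so they
    bind the mature, spliced transcript).
    """
    ga, gb = alignment
    if len(ga) != len(gb):
        raise ValueError("gapped strings differ in length")
    n = len(ga)
    arr_a = np.frombuffer(ga.encode(), dtype="S1")
    arr_b = np.frombuffer(gb.encode(), dtype="S1")
    is_gap = (arr_a == b"-") | (arr_b == b"-")
    is_n = (arr_a == b"N") | (arr_b == b"N")
    mism = (arr_a != arr_b) & ~is_gap
    gc_col = ((arr_b == b"G") | (arr_b == b"C")) & ~is_gap

    gap_cum = np.concatenate([[0], np.cumsum(is_gap)])
    n_cum = np.concatenate([[0], np.cumsum(is_n)])
    mism_cum = np.concatenate([[0], np.cumsum(mism)])
    gc_cum = np.concatenate([[0], np.cumsum(gc_col)])
    # sequence offset of each column (index of the residue in the ungapped seq)
    off_a = np.cumsum(arr_a != b"-") - 1
    off_b = np.cumsum(arr_b != b"-") - 1
    bnd_a = sorted(boundaries_a)
    bnd_b = sorted(boundaries_b)

    windows: list[CandidateWindow] = []
    for length in range(c.min_len, c.max_len + 1):
        for start in range(0, n - length + 1):
            end = start + length
            if gap_cum[end] - gap_cum[start] > 0:
                continue  # windows spanning a gap are not candidate probes
            oa = int(off_a[start])
            ob = int(off_b[start])
            n_mism = int(mism_cum[end] - mism_cum[start])
            has_n = bool(n_cum[end] - n_cum[start])
            gc_b = float(gc_cum[end] - gc_cum[start]) / length
            reason = None
            if has_n:
                reason = "contains N"
            elif any(oa < j < oa + length for j in bnd_a) or any(
                ob < j < ob + length for j in bnd_b
            ):
                reason = "spans exon boundary"
            elif n_mism > c.max_mismatches:
                reason = f"{n_mism} mismatches > {c.max_mismatches}"
            if reason is None:
                positions = tuple(
                    int(p) for p in np.flatnonzero(mism[start:end])
                )
            else:
                positions = ()
            windows.append(
                CandidateWindow(
                    gene=gene,
                    offset_a=oa,
                    offset_b=ob,
                    length=length,
                    seq_a=ga[start:end],
                    seq_b=gb[start:end],
                    mismatch_positions=positions,
                    gc_b=gc_b,
                    feasible=reason is None,
                    infeasible_reason=reason,
                )
            )
    return windows


def best_shared_window(
    windows: Sequence[CandidateWindow], c: DesignConstraints
) -> CandidateWindow | None:
    """Minimum-score feasible window; ties broken by fewer mismatches,
    then longer window, then smaller species-B offset."""
    best: CandidateWindow | None = None
    best_key: tuple | None = None
    for w in windows:
        if not w.feasible:
            continue
        s = score_window(w, c)
        key = (s, len(w.mismatch_positions), -w.length, w.offset_b)
        if best_key is None or key < best_key:
            best, best_key = replace(w, score=s), key
    return best


def _best_single_species_window(
    seq: str,
    c: DesignConstraints,
    boundaries: frozenset[int] | Iterable[int] = frozenset(),
) -> tuple[int, int, str, float] | None:
    """Best (offset, length, window seq, score) of one sequence, scored on
    GC deviation alone.  Returns None when no window is admissible."""
    bnd = sorted(boundaries)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    gc_cum = np.concatenate(
        [[0], np.cumsum((arr == b"G") | (arr == b"C"))]
    )
    n_cum = np.concatenate([[0], np.cumsum(arr == b"N")])
    best = None
    best_key = None
    for length in range(c.min_len, c.max_len + 1):
        for start in range(0, len(seq) - length + 1):
            end = start + length
            if n_cum[end] - n_cum[start]:
                continue
            if any(start < j < end for j in bnd):
                continue
            gc = float(gc_cum[end] - gc_cum[start]) / length
            score = c.weight_gc * abs(gc - c.gc_target)
            key = (score, -length, start)
            if best_key is None or key < best_key:
                best = (start, length, seq[start:end], score)
                best_key = key
    return best


def _specific_probe(
    gene: str,
    species: str,
    seq: str,
    c: DesignConstraints,
    boundaries: frozenset[int] | Iterable[int],
    quantifiable: bool,
) -> ProbeRecord | None:
    if len(seq) < c.min_len:
        return None
    found = _best_single_species_window(seq, c, boundaries)
    if found is None:
        return None
    _, _, window_seq, score = found
    return ProbeRecord(
        probe_id=f"{gene}_{species}",
        genes=(gene,),
        scope=f"specific_{species}",
        sequence=window_seq,
        source_species=species,
        gc=gc_fraction(window_seq),
        mismatches_vs_other_species=None,
        design_score=score,
    )


def select_probe(
    pair: OrthologPair, c: DesignConstraints | None = None
) -> tuple[list[ProbeRecord], DesignDecision]:
    """Design the probe(s) for one ortholog pair.

    Returns one shared probe when some alignment window meets every
    constraint, otherwise one species-specific probe per species (scored
    on GC deviation alone).  A gene shorter than ``min_len`` in one
    species yields a single specific probe for the longer species.
    """
    c = c or DesignConstraints()
    quantifiable = pair.category in QUANTIFIABLE_CATEGORIES
    short_a = len(pair.seq_a) < c.min_len
    short_b = len(pair.seq_b) < c.min_len

    if short_a and short_b:
        decision = DesignDecision(
            gene=pair.gene, category=pair.category, n_feasible_windows=0,
            decision="none",
            reason=f"gene shorter than {c.min_len} nt in both species",
        )
        return [], decision

    if short_a or short_b:
        species = "B" if short_a else "A"
        seq = pair.seq_b if short_a else pair.seq_a
        bnd = pair.boundaries_b if short_a else pair.boundaries_a
        logger.warning(
            "gene %s shorter than %d nt in species %s; designing a "
            "species-%s probe only", pair.gene, c.min_len,
            "A" if short_a else "B", species,
        )
        probe = _specific_probe(pair.gene, species, seq, c, bnd, quantifiable)
        probes = [replace(probe, quantifiable=quantifiable)] if probe else []
        decision = DesignDecision(
            gene=pair.gene, category=pair.category, n_feasible_windows=0,
            decision=f"specific_{species}" if probes else "none",
            reason=f"too short in species {'A' if short_a else 'B'}",
        )
        return probes, decision

    alignment = align_pair(pair.seq_a, pair.seq_b)
    windows = enumerate_windows(
        alignment, c, pair.gene, pair.boundaries_a, pair.boundaries_b
    )
    n_feasible = sum(w.feasible for w in windows)
    best = best_shared_window(windows, c)
    if best is not None:
        probe = ProbeRecord(
            probe_id=f"{pair.gene}_shared",
            genes=(pair.gene,),
            scope="shared",
            sequence=best.seq_b,
            source_species="B",
            gc=best.gc_b,
            mismatches_vs_other_species=len(best.mismatch_positions),
            design_score=best.score,
            quantifiable=quantifiable,
        )
        decision = DesignDecision(
            gene=pair.gene, category=pair.category,
            n_feasible_windows=n_feasible, decision="shared",
            reason="feasible shared window found",
            chosen_offset_b=best.offset_b, chosen_length=best.length,
            chosen_mismatches=len(best.mismatch_positions),
            chosen_score=best.score,
        )
        return [probe], decision

    probes = []
    for species, seq, bnd in (
        ("A", pair.seq_a, pair.boundaries_a),
        ("B", pair.seq_b, pair.boundaries_b),
    ):
        probe = _specific_probe(pair.gene, species, seq, c, bnd, quantifiable)
        if probe is not None:
            probes.append(replace(probe, quantifiable=quantifiable))
    decision = DesignDecision(
        gene=pair.gene, category=pair.category, n_feasible_windows=0,
        decision="specific_both" if len(probes) == 2 else (
            f"specific_{probes[0].source_species}" if probes else "none"
        ),
        reason="no shared window satisfies all constraints",
    )
    return probes, decision


def design_probe_set(
    rec_a: GenomeRecord,
    rec_b: GenomeRecord,
    editing_a: Mapping | None = None,
    editing_b: Mapping | None = None,
    name_map: Mapping[str, str] | None = None,
    c: DesignConstraints | None = None,
) -> ProbeSet:
    """Design the full probe set for a genome pair.

    Orthologs are paired by symbol, each species' editing table applied to
    its own sequences, and one shared or two specific probes designed per
    paired gene; single-species genes receive a species-specific probe.
    tRNA/rRNA genes receive probes but are flagged non-quantifiable.
    Output is deterministic for fixed inputs.
    """
    c = c or DesignConstraints()
    pairing = pair_orthologs(
        rec_a, rec_b, name_map=name_map, editing_a=editing_a,
        editing_b=editing_b,
    )
    probe_set = ProbeSet()
    for pair in pairing.pairs:
        probes, decision = select_probe(pair, c)
        probe_set.probes.extend(probes)
        probe_set.design_report.append(decision)
    for gene in pairing.unpaired:
        probe_set.probes.extend(_design_unpaired(gene, c))
        probe_set.design_report.append(
            DesignDecision(
                gene=gene.gene, category=gene.category, n_feasible_windows=0,
                decision=f"specific_{gene.species}",
                reason=f"gene present only in species {gene.species}",
            )
        )
    return probe_set


def _design_unpaired(gene: UnpairedGene, c: DesignConstraints) -> list[ProbeRecord]:
    quantifiable = gene.category in QUANTIFIABLE_CATEGORIES
    probe = _specific_probe(
        gene.gene, gene.species, gene.seq, c, gene.boundaries, quantifiable
    )
    if probe is None:
        logger.warning("gene %s (species %s): no admissible window", gene.gene,
                       gene.species)
        return []
    return [replace(probe, quantifiable=quantifiable)]


# ---------------------------------------------------------------------------
# serialization

PROBE_TSV_COLUMNS = [
    "probe_id", "genes", "scope", "sequence", "source_species", "length",
    "gc", "mismatches_vs_other_species", "design_score", "quantifiable",
]


def write_probe_tsv(path: str | Path, probe_set: ProbeSet) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(PROBE_TSV_COLUMNS) + "\n")
        for p in probe_set.probes:
            mism = "" if p.mismatches_vs_other_species is None else str(
                p.mismatches_vs_other_species
            )
            handle.write(
                f"{p.probe_id}\t{','.join(p.genes)}\t{p.scope}\t{p.sequence}\t"
                f"{p.source_species}\t{p.length}\t{p.gc:.6f}\t{mism}\t"
                f"{p.design_score:.6f}\t{int(p.quantifiable)}\n"
            )


def write_probe_fasta(path: str | Path, probe_set: ProbeSet) -> None:
    with open(path, "w") as handle:
        for p in probe_set.probes:
            handle.write(f">{p.probe_id}|{','.join(p.genes)}|{p.scope}\n")
            handle.write(p.sequence + "\n")


def write_design_report(path: str | Path, probe_set: ProbeSet) -> None:
    cols = [
        "gene", "category", "n_feasible_windows", "decision", "reason",
        "chosen_offset_b", "chosen_length", "chosen_mismatches", "chosen_score",
    ]
    with open(path, "w") as handle:
        handle.write("\t".join(cols) + "\n")
        for d in probe_set.design_report:
            vals = [
                d.gene, d.category, str(d.n_feasible_windows), d.decision,
                d.reason,
                "" if d.chosen_offset_b is None else str(d.chosen_offset_b),
                "" if d.chosen_length is None else str(d.chosen_length),
                "" if d.chosen_mismatches is None else str(d.chosen_mismatches),
                "" if d.chosen_score is None else f"{d.chosen_score:.6f}",
            ]
            handle.write("\t".join(vals) + "\n")


def validate_probe_set(
    probe_set: ProbeSet, c: DesignConstraints | None = None
) -> dict:
    """QC summary of a probe set: headline counts plus constraint violations.

    Checks every probe for length in [min_len, max_len] and every shared
    probe for a mismatch count within budget.
    """
    c = c or DesignConstraints()
    bad_length = [
        p.probe_id for p in probe_set.probes
        if not (c.min_len <= p.length <= c.max_len)
    ]
    bad_mismatch = [
        p.probe_id for p in probe_set.probes
        if p.scope == "shared"
        and (p.mismatches_vs_other_species is None
             or p.mismatches_vs_other_species > c.max_mismatches)
    ]
    out = probe_set.summary()
    out.update(
        {
            "length_violations": bad_length,
            "mismatch_violations": bad_mismatch,
            "qc_pass": not bad_length and not bad_mismatch,
        }
    )
    return out
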