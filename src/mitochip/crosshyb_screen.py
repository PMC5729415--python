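"""Cross-hybridization screening of probes against decoy sequences.

Plant mitochondrial genomes carry tRNA genes nearly identical to
plastid-encoded ones, so probes for them pick up plastid signal.  This
module aligns each probe locally against a decoy set (e.g. the plastid
genome), on both strands, and flags probes whose best identity — counted
as aligned matching bases divided by the full probe length, so partial
matches score proportionally — reaches a threshold (default 0.70, the low
end of the identity range observed between mitochondrial and plastid
tRNAs).  Flagged probes are only marked, never removed: exclusion from
interpretation is the quantification layer's decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align

from mitochip.genome_io import reverse_complement
from mitochip.probe_design import ProbeRecord

DEFAULT_THRESHOLD = 0.70


@dataclass(frozen=True)
class CrossHybReport:
    probe_id: str
    best_decoy: str
    best_identity: float
    flagged: bool


def _make_aligner() -> Align.PairwiseAligner:
    # stringent gap costs: gappy local alignments otherwise inflate the
    # match count of unrelated sequences toward the flagging threshold
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _best_identity(
    probe_seq: str, decoys: Mapping[str, str], aligner: Align.PairwiseAligner
) -> tuple[str, float]:
    best_decoy, best_ident = "", 0.0
    queries = (probe_seq, reverse_complement(probe_seq))
    for decoy_id, decoy_seq in decoys.items():
        for query in queries:
            alignments = aligner.align(decoy_seq, query)
            if len(alignments) == 0:
                continue
            counts = alignments[0].counts()
            ident = counts.identities / len(probe_seq)
            if ident > best_ident:
                best_decoy, best_ident = decoy_id, ident
    return best_decoy, best_ident


def screen_probe(
    probe: ProbeRecord | str,
    decoys: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    probe_id: str = "probe",
) -> CrossHybReport:
    """Best-identity report of one probe against a decoy sequence set.

    Both the probe and its reverse complement are searched so that
    antisense similarity is caught.  Raises on an empty decoy set.
    """
    if not decoys:
        raise ValueError("decoy set is empty")
    if isinstance(probe, ProbeRecord):
        seq, probe_id = probe.sequence, probe.probe_id
    else:
        seq = probe
    aligner = _make_aligner()
    best_decoy, best_ident = _best_identity(seq, decoys, aligner)
    return CrossHybReport(
        probe_id=probe_id,
        best_decoy=best_decoy,
        best_identity=best_ident,
        flagged=best_ident >= threshold,
    )


def screen_probes(
    probes: Sequence[ProbeRecord] | Mapping[str, str],
    decoys: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[CrossHybReport]:
    """Screen every probe; accepts ProbeRecords or an id -> sequence mapping."""
    if not decoys:
        raise ValueError("decoy set is empty")
    aligner = _make_aligner()
    if isinstance(probes, Mapping):
        items = list(probes.items())
    else:
        items = [(p.probe_id, p.sequence) for p in probes]
    reports = []
    for probe_id, seq in items:
        best_decoy, best_ident = _best_identity(seq, decoys, aligner)
        reports.append(
            CrossHybReport(
                probe_id=probe_id,
                best_decoy=best_decoy,
                best_identity=best_ident,
                flagged=best_ident >= threshold,
            )
        )
    return reports


def write_crosshyb_tsv(path: str | Path, reports: Sequence[CrossHybReport]) -> None:
    with open(path, "w") as handle:
        handle.write("probe_id\tbest_decoy\tbest_identity\tflagged\n")
        for r in reports:
            handle.write(
                f"{r.probe_id}\t{r.best_decoy}\t{r.best_identity:.4f}\t"
                f"{int(r.flagged)}\n"
            )
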