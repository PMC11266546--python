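"""Dataset assembly and the 30%-sequence-similarity leakage barrier.

Train/test splits of stability data leak badly when homologous proteins
appear on both sides; below ~30% identity (the "twilight zone") most
protein pairs adopt different folds, so the barrier removes every training
protein whose identity to any test protein reaches the threshold.

Two interchangeable backends compute identities: the external MMseqs2
binary, invoked with the reference flags ``-c 0.3 -s 7.5 --seq-id-mode 1``
when present on PATH, and a built-in global aligner (BLOSUM62, affine gap
open 11 / extend 1, identity = matches / alignment length) that needs no
binary.  The backend used is recorded in every report, and a post-split
audit recomputes all cross-split identities with the built-in aligner.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import write_fasta
from .thermo_augment import DdgRecord, dedup_max_abs

logger = logging.getLogger(__name__)

__all__ = ["DatasetSplit", "sequence_identity", "homology_filter",
           "assemble_training_set", "filter_cdna_subset", "audit_split"]

IDENTITY_THRESHOLD = 0.30
MMSEQS_FLAGS = ["-c", "0.3", "-s", "7.5", "--seq-id-mode", "1"]


@dataclass
class DatasetSplit:
    train: list[DdgRecord]
    test: list[DdgRecord]
    similarity_report: dict[str, float]   # candidate protein -> max identity
    removed: list[str] = field(default_factory=list)
    backend: str = "builtin"
    stage_counts: dict[str, int] = field(default_factory=dict)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _builtin_max_identities(candidate_seqs: dict[str, str],
                            reference_seqs: dict[str, str]
                            ) -> dict[str, float]:
    out = {}
    for name, seq in candidate_seqs.items():
        out[name] = max((sequence_identity(seq, ref)
                         for ref in reference_seqs.values()), default=0.0)
    return out


def _mmseqs_max_identities(candidate_seqs: dict[str, str],
                           reference_seqs: dict[str, str]
                           ) -> dict[str, float]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fasta(candidate_seqs, tmp / "query.fasta")
        write_fasta(reference_seqs, tmp / "target.fasta")
        out = tmp / "hits.tsv"
        subprocess.run(
            ["mmseqs", "easy-search", str(tmp / "query.fasta"),
             str(tmp / "target.fasta"), str(out), str(tmp / "work"),
             *MMSEQS_FLAGS, "--format-output", "query,target,fident"],
            check=True, capture_output=True)
        best = {name: 0.0 for name in candidate_seqs}
        for line in out.read_text().splitlines():
            q, _t, fid = line.split("\t")[:3]
            best[q] = max(best[q], float(fid))
        return best


def homology_filter(candidate_records: list[DdgRecord],
                    candidate_seqs: dict[str, str],
                    reference_seqs: dict[str, str],
                    threshold: float = IDENTITY_THRESHOLD,
                    backend: str = "auto",
                    ) -> tuple[list[DdgRecord], dict]:
    """Drop candidate proteins at >= threshold identity to any reference.

    Every record of a removed protein is removed with it.  Returns the
    surviving records plus a report with per-protein max identities, the
    removed protein list and the backend used.
    """
    missing = {r.protein_id for r in candidate_records} - set(candidate_seqs)
    if missing:
        raise ValueError(f"no sequence for protein(s): {sorted(missing)}")
    if not reference_seqs:
        return list(candidate_records), {
            "backend": "none", "max_identity": {}, "removed": []}
    use_mmseqs = (backend == "mmseqs"
                  or (backend == "auto" and shutil.which("mmseqs")))
    if use_mmseqs:
        ident = _mmseqs_max_identities(candidate_seqs, reference_seqs)
        used = "mmseqs"
    else:
        ident = _builtin_max_identities(candidate_seqs, reference_seqs)
        used = "builtin"
    removed = {name for name, v in ident.items() if v >= threshold}
    kept = [r for r in candidate_records if r.protein_id not in removed]
    if removed:
        logger.info("homology filter (%s) removed %d protein(s): %s",
                    used, len(removed), sorted(removed))
    return kept, {"backend": used, "max_identity": ident,
                  "removed": sorted(removed)}


def assemble_training_set(sources: list[list[DdgRecord]],
                          test_records: list[DdgRecord],
                          candidate_seqs: dict[str, str],
                          reference_seqs: dict[str, str],
                          threshold: float = IDENTITY_THRESHOLD,
                          backend: str = "auto") -> DatasetSplit:
    """Concatenate sources, dedup by max |ΔΔG|, homology-filter vs the test set."""
    concatenated: list[DdgRecord] = [r for src in sources for r in src]
    deduped = dedup_max_abs(concatenated)
    filtered, report = homology_filter(deduped, candidate_seqs,
                                       reference_seqs, threshold, backend)
    counts = {"concatenated": len(concatenated), "deduplicated": len(deduped),
              "homology_filtered": len(filtered)}
    logger.info("assembly stage counts: %s", counts)
    return DatasetSplit(train=filtered, test=list(test_records),
                        similarity_report=report["max_identity"],
                        removed=report["removed"], backend=report["backend"],
                        stage_counts=counts)


def audit_split(split: DatasetSplit, train_seqs: dict[str, str],
                test_seqs: dict[str, str],
                threshold: float = IDENTITY_THRESHOLD) -> float:
    """Recompute all cross-split identities (builtin backend); return the max.

    Raises if any pair reaches the threshold — the split leaks.
    """
    train_proteins = {r.protein_id for r in split.train}
    max_ident = 0.0
    for p in sorted(train_proteins):
        for ref in test_seqs.values():
            max_ident = max(max_ident, sequence_identity(train_seqs[p], ref))
    if max_ident >= threshold:
        raise ValueError(f"split audit failed: max cross-split identity "
                         f"{max_ident:.3f} >= {threshold}")
    return max_ident


REQUIRED_CDNA_COLUMNS = {"domain_class", "protein_id", "mutation",
                         "wt_pdb_id", "ddg"}


def filter_cdna_subset(table, reference_seqs: dict[str, str] | None = None,
                       candidate_seqs: dict[str, str] | None = None,
                       threshold: float = IDENTITY_THRESHOLD
                       ) -> list[DdgRecord]:
    """Select usable records from a proteolysis-derived stability table.

    Keeps natural domains only, single-point substitutions only (mutation
    strings like ``A10V``; multi-mutants such as ``A10V:G20S`` are
    excluded), and rows with a wild-type PDB id; optionally
    homology-filters the survivors against a reference sequence set.
    """
    import re

    missing = REQUIRED_CDNA_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"cDNA table lacks columns: {sorted(missing)}")
    single = re.compile(r"^([A-Y])(\d+)([A-Y])$")
    records: list[DdgRecord] = []
    for row in table.itertuples(index=False):
        if str(row.domain_class).lower().replace(" ", "") != "natural":
            continue
        pdb = str(row.wt_pdb_id).strip()
        if not pdb or pdb.lower() == "nan":
            continue
        m = single.match(str(row.mutation).strip())
        if m is None:
            continue
        records.append(DdgRecord(
            protein_id=str(row.protein_id),
            chain=str(getattr(row, "chain", "") or ""),
            position=int(m.group(2)), from_aa=m.group(1), to_aa=m.group(3),
            ddg=float(row.ddg), provenance="original", source="cdna",
            pdb_id=pdb))
    if reference_seqs:
        if candidate_seqs is None:
            raise ValueError("candidate sequences required for homology "
                             "filtering")
        records, _ = homology_filter(records, candidate_seqs,
                                     reference_seqs, threshold)
    return records
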