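"""Thermodynamic data augmentation for ΔΔG tables.

Gibbs free energy is a state function, so measured mutations at one
position imply further thermodynamically valid ones:

* Thermodynamic reversibility (TR): swapping the wild-type and mutant
  amino acids negates ΔΔG — one extra record per original.
* Thermodynamic permutations (TP): with n distinct mutant amino acids
  characterized at one position, every ordered pair (a_i -> a_j) has
  ΔΔG = ΔΔG(wt -> a_j) - ΔΔG(wt -> a_i), yielding n(n-1) new records that
  never involve the wild type on either side and whose ΔΔG multiset is
  closed under negation (mean exactly zero).

Duplicate measurements across source tables are resolved by keeping the
one with the largest |ΔΔG| (stable tie-break: first in input order), and
deduplication precedes TP so that n counts distinct mutant amino acids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from ._tables import AA_INDEX

logger = logging.getLogger(__name__)

__all__ = ["DdgRecord", "reverse", "permute", "dedup_max_abs",
           "augment_dataset", "records_to_frame", "frame_to_records",
           "read_csv", "write_csv"]

CSV_COLUMNS = ["protein_id", "pdb_id", "chain", "position", "from_aa",
               "to_aa", "ddg", "provenance", "source"]


@dataclass(frozen=True)
class DdgRecord:
    protein_id: str
    chain: str
    position: int              # author numbering
    from_aa: str
    to_aa: str
    ddg: float                 # kcal/mol, positive = destabilizing
    provenance: str = "original"     # original | TR | TP
    source: str = ""
    pdb_id: str = ""

    def __post_init__(self):
        if self.from_aa == self.to_aa:
            raise ValueError("from_aa and to_aa must differ")
        for aa in (self.from_aa, self.to_aa):
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino acid code {aa!r}")
        if self.provenance not in ("original", "TR", "TP"):
            raise ValueError(f"bad provenance {self.provenance!r}")

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.protein_id, self.chain, self.position)

    @property
    def mutation_key(self) -> tuple[str, str, int, str, str]:
        return (self.protein_id, self.chain, self.position,
                self.from_aa, self.to_aa)


def reverse(record: DdgRecord) -> DdgRecord:
    """TR: swap from/to and negate ΔΔG."""
    return replace(record, from_aa=record.to_aa, to_aa=record.from_aa,
                   ddg=-record.ddg, provenance="TR")


def permute(records: list[DdgRecord]) -> list[DdgRecord]:
    """TP at one site: all n(n-1) ordered pairs among the n mutant AAs.

    Inputs must be original, deduplicated records at a single
    (protein, chain, position) sharing one wild type.
    """
    if not records:
        return []
    sites = {r.site for r in records}
    if len(sites) > 1:
        raise ValueError(f"records span multiple sites: {sorted(sites)}")
    if any(r.provenance != "original" for r in records):
        raise ValueError("TP inputs must be original measurements")
    wts = {r.from_aa for r in records}
    if len(wts) > 1:
        raise ValueError(
            f"conflicting wild types {sorted(wts)} at {records[0].site}: "
            "thermodynamic validity needs a single reference state")
    tos = [r.to_aa for r in records]
    if len(set(tos)) != len(tos):
        raise ValueError("duplicate mutant amino acids at one site; "
                         "run dedup_max_abs first")
    out = []
    for ri in records:
        for rj in records:
            if ri.to_aa == rj.to_aa:
                continue
            out.append(replace(ri, from_aa=ri.to_aa, to_aa=rj.to_aa,
                               ddg=rj.ddg - ri.ddg, provenance="TP"))
    return out


def dedup_max_abs(records: list[DdgRecord]) -> list[DdgRecord]:
    """Collapse identical mutations to the record with max |ΔΔG|.

    Exact-|ΔΔG| ties keep the first in input order; output preserves the
    input order of the surviving records (idempotent).
    """
    best: dict[tuple, DdgRecord] = {}
    order: list[tuple] = []
    for r in records:
        key = r.mutation_key
        prev = best.get(key)
        if prev is None:
            best[key] = r
            order.append(key)
        elif abs(r.ddg) > abs(prev.ddg):
            best[key] = r
    return [best[k] for k in order]


def augment_dataset(records: list[DdgRecord],
                    modes: set[str] | frozenset[str] = frozenset({"TP", "TR"}),
                    ) -> tuple[list[DdgRecord], dict]:
    """Original records plus requested TP/TR augmentations, with counts.

    Generated records colliding with an existing (protein, chain, position,
    from, to) mutation are dropped in favor of the experimental original
    and counted in the report.
    """
    bad = set(modes) - {"TP", "TR"}
    if bad:
        raise ValueError(f"unknown augmentation modes {sorted(bad)}")
    existing = {r.mutation_key for r in records}
    out = list(records)
    report = {"original": len(records), "TP": 0, "TR": 0, "collisions": 0}

    generated: list[DdgRecord] = []
    if "TP" in modes:
        by_site: dict[tuple, list[DdgRecord]] = {}
        for r in records:
            if r.provenance == "original":
                by_site.setdefault(r.site, []).append(r)
        for site_records in by_site.values():
            generated.extend(permute(site_records))
    if "TR" in modes:
        generated.extend(reverse(r) for r in records
                         if r.provenance == "original")

    for g in generated:
        if g.mutation_key in existing:
            report["collisions"] += 1
            continue
        existing.add(g.mutation_key)
        out.append(g)
        report[g.provenance] += 1
    report["total"] = len(out)
    if report["collisions"]:
        logger.info("dropped %d generated records colliding with originals",
                    report["collisions"])
    return out, report


# -- CSV schema -----------------------------------------------------------

def records_to_frame(records: list[DdgRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.pdb_id, r.chain, r.position, r.from_aa, r.to_aa,
          r.ddg, r.provenance, r.source) for r in records],
        columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[DdgRecord]:
    missing = {"protein_id", "position", "from_aa", "to_aa", "ddg"} - set(df.columns)
    if missing:
        raise ValueError(f"ΔΔG table lacks required columns: {sorted(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        chain = getattr(row, "chain", "") or ""
        if chain == "":
            logger.warning("record %s/%s lacks a chain; keyed protein-wide",
                           row.protein_id, row.position)
        recs.append(DdgRecord(
            protein_id=str(row.protein_id), chain=str(chain),
            position=int(row.position), from_aa=str(row.from_aa),
            to_aa=str(row.to_aa), ddg=float(row.ddg),
            provenance=str(getattr(row, "provenance", "original") or "original"),
            source=str(getattr(row, "source", "") or ""),
            pdb_id=str(getattr(row, "pdb_id", "") or "")))
    return recs


def read_csv(path: str | Path) -> list[DdgRecord]:
    return frame_to_records(pd.read_csv(path, keep_default_na=False))


def write_csv(records: list[DdgRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
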