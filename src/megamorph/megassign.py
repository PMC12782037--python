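"""OTU-to-specimen taxonomic assignment and recovery-rate accounting.

Single-specimen megabarcoding yields, per specimen, one sequencing sample
(two when a PCR was repeated) holding a handful of OTUs with read counts
and database taxonomy. The assignment rule set:

1. keep only macroinvertebrate OTUs (taxonomic filtering),
2. for a repeated specimen, use the sample whose top OTU has more reads,
3. the OTU with most reads wins; assignments under ``min_reads`` (default
   1,000) are discarded as ``insufficient_reads``,
4. a winner whose order contradicts the morphological identification is
   removed as ``order_mismatch`` (no fallback to the next-best OTU),
5. a winner without a species-level name is ``no_species_hit``.

The summary reports the sequence recovery rate — the fraction of specimens
yielding a taxonomically valid read at all — and the species-level
assignment rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthgen import TaxonLabel

STATUSES = ("assigned", "insufficient_reads", "order_mismatch", "no_species_hit")


class MissingSampleError(ValueError):
    """Raised when a specimen has no sequencing sample at all."""


@dataclass(frozen=True)
class AssignmentResult:
    specimen_id: str
    status: str
    taxon: TaxonLabel | None
    otu_id: str | None
    reads: int
    sample_id: str | None


@dataclass(frozen=True)
class AssignmentSummary:
    n_total: int
    n_assigned: int
    n_insufficient: int
    n_mismatch: int
    n_nospecies: int

    def __post_init__(self) -> None:
        parts = self.n_assigned + self.n_insufficient + self.n_mismatch + self.n_nospecies
        if parts != self.n_total:
            raise ValueError(f"status counts {parts} do not partition n_total {self.n_total}")

    @property
    def recovery_rate(self) -> float:
        """Fraction of specimens yielding enough reads for any assignment."""
        return (self.n_total - self.n_insufficient) / self.n_total

    @property
    def species_rate(self) -> float:
        """Fraction of specimens assigned to species level."""
        return self.n_assigned / self.n_total


def _filter_macroinvertebrates(records: pd.DataFrame) -> pd.DataFrame:
    if "macroinvertebrate" in records.columns:
        return records[records["macroinvertebrate"].astype(bool)]
    return records


def resolve_repeats(samples: pd.DataFrame) -> str:
    """Pick the sample whose top macroinvertebrate OTU has more reads.

    Ties break toward the lexicographically smaller sample_id; a sample with
    no macroinvertebrate OTUs counts as 0 reads.
    """
    ids = sorted(samples["sample_id"].unique())
    if not ids:
        raise MissingSampleError("specimen has no sequencing samples")
    if len(ids) == 1:
        return ids[0]
    kept = _filter_macroinvertebrates(samples)
    top = {sid: 0 for sid in ids}
    for sid, grp in kept.groupby("sample_id"):
        top[str(sid)] = int(grp["reads"].max())
    best = max(top[sid] for sid in ids)
    return min(sid for sid in ids if top[sid] == best)


def assign_specimen(
    records: pd.DataFrame, morphological_order: str, min_reads: int = 1000
) -> AssignmentResult:
    """Apply the winner-takes-all rules to one specimen's chosen sample."""
    specimen_id = str(records["specimen_id"].iloc[0]) if len(records) else ""
    sample_id = str(records["sample_id"].iloc[0]) if len(records) else None
    kept = _filter_macroinvertebrates(records)
    if kept.empty:
        return AssignmentResult(specimen_id, "insufficient_reads", None, None, 0, sample_id)
    # max reads wins; ties toward lexicographically smaller otu_id
    kept = kept.sort_values(["reads", "otu_id"], ascending=[False, True])
    win = kept.iloc[0]
    reads = int(win["reads"])
    taxon = TaxonLabel(
        species=str(win["species"]) if pd.notna(win["species"]) else "",
        genus=str(win["genus"]) if pd.notna(win["genus"]) else "",
        family=str(win["family"]) if pd.notna(win["family"]) else "",
        order=str(win["order"]) if pd.notna(win["order"]) else "",
    )
    base = dict(
        specimen_id=str(win["specimen_id"]),
        otu_id=str(win["otu_id"]),
        reads=reads,
        sample_id=str(win["sample_id"]),
    )
    if reads < min_reads:
        return AssignmentResult(status="insufficient_reads", taxon=None, **base)
    if taxon.order != morphological_order:
        return AssignmentResult(status="order_mismatch", taxon=taxon, **base)
    if taxon.species == "":
        return AssignmentResult(status="no_species_hit", taxon=taxon, **base)
    return AssignmentResult(status="assigned", taxon=taxon, **base)


def assign_all(
    otu_table: pd.DataFrame, morphology: pd.DataFrame, min_reads: int = 1000
) -> tuple[list[AssignmentResult], AssignmentSummary]:
    """Resolve repeats and assign every specimen in the morphology table.

    A specimen present morphologically but absent from the OTU table is
    recorded as ``insufficient_reads`` with 0 reads (it returned nothing).
    """
    results: list[AssignmentResult] = []
    by_specimen = dict(tuple(otu_table.groupby("specimen_id"))) if len(otu_table) else {}
    for row in morphology.sort_values("specimen_id").itertuples():
        sid = str(row.specimen_id)
        grp = by_specimen.get(sid)
        if grp is None or grp.empty:
            results.append(AssignmentResult(sid, "insufficient_reads", None, None, 0, None))
            continue
        chosen = resolve_repeats(grp)
        records = grp[grp["sample_id"] == chosen]
        res = assign_specimen(records, str(row.morphological_order), min_reads)
        if res.specimen_id == "":  # chosen sample had rows filtered to nothing
            res = AssignmentResult(sid, "insufficient_reads", None, None, 0, chosen)
        results.append(res)
    counts = {s: sum(r.status == s for r in results) for s in STATUSES}
    summary = AssignmentSummary(
        n_total=len(results),
        n_assigned=counts["assigned"],
        n_insufficient=counts["insufficient_reads"],
        n_mismatch=counts["order_mismatch"],
        n_nospecies=counts["no_species_hit"],
    )
    return results, summary


def assignments_table(results: list[AssignmentResult]) -> pd.DataFrame:
    """assignments.csv content."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in results],
            "status": [r.status for r in results],
            "order": [r.taxon.order if r.taxon else "" for r in results],
            "family": [r.taxon.family if r.taxon else "" for r in results],
            "genus": [r.taxon.genus if r.taxon else "" for r in results],
            "species": [r.taxon.species if r.taxon else "" for r in results],
            "otu_id": [r.otu_id or "" for r in results],
            "reads": [r.reads for r in results],
            "sample_id": [r.sample_id or "" for r in results],
        }
    )


def summary_dict(summary: AssignmentSummary) -> dict:
    return {
        "n_total": summary.n_total,
        "n_assigned": summary.n_assigned,
        "n_insufficient": summary.n_insufficient,
        "n_mismatch": summary.n_mismatch,
        "n_nospecies": summary.n_nospecies,
        "recovery_rate": summary.recovery_rate,
        "species_rate": summary.species_rate,
    }
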