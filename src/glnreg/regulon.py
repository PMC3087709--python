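"""Integration of binding, response and dependence evidence into a regulon.

Each gene with any evidence is classified into one of four categories:

* **i** — nitrogen-responsive, regulator-dependent, and bound (the
  regulator sits at its promoter): a direct target;
* **ii** — responsive and dependent but not bound: likely regulated through
  an intermediate;
* **iii** — responsive but regulator-independent;
* **iv** — bound but showing no transcriptional response under the
  conditions studied;
* **none** — anything else (including genes responsive in neither strain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from glnreg.peaks import BindingRegion

CATEGORIES = ("i", "ii", "iii", "iv", "none")


@dataclass(frozen=True)
class RegulonRecord:
    gene_id: str
    bound: bool
    responsive: bool
    dependent: bool
    category: str
    region_ids: tuple[str, ...] = ()
    motif_status: str = ""
    flags: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _category(bound: bool, responsive: bool, dependent: bool) -> str:
    if responsive and dependent:
        return "i" if bound else "ii"
    if responsive:
        return "iii"
    if bound:
        return "iv"
    return "none"


def classify(dependence_calls: pd.DataFrame,
             binding_regions: Sequence[BindingRegion],
             motif_table: pd.DataFrame | None = None) -> list[RegulonRecord]:
    """Join dependence calls and binding evidence into regulon records.

    ``dependence_calls`` is the output of :func:`glnreg.expression.dependence`
    (indexed by gene id, with ``wt_passes`` and ``dependent`` columns); a
    gene is *bound* when it is a target of any reported binding region at
    any timepoint.  Every gene appearing in either input is classified; the
    result is independent of input order.  Genes that are binding targets
    only (no expression data) are classified with ``responsive=False`` and
    flagged ``no_expression_data``; duplicate gene ids in the calls raise.
    """
    if dependence_calls.index.has_duplicates:
        dup = dependence_calls.index[
            dependence_calls.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in dependence calls: {dup}")

    gene_regions: dict[str, list[str]] = {}
    for region in binding_regions:
        if region.present_in_control:
            continue
        for gid in region.target_gene_ids:
            gene_regions.setdefault(gid, []).append(
                region.region_id or f"{region.replicon}:{region.start}-{region.end}")

    motif_by_region: dict[str, str] = {}
    if motif_table is not None:
        motif_by_region = dict(zip(motif_table["region_id"],
                                   motif_table["sites"]))

    records: list[RegulonRecord] = []
    all_genes = sorted(set(dependence_calls.index.astype(str))
                       | set(gene_regions))
    for gid in all_genes:
        bound = gid in gene_regions
        region_ids = tuple(sorted(set(gene_regions.get(gid, ()))))
        has_expr = gid in dependence_calls.index
        if has_expr:
            row = dependence_calls.loc[gid]
            responsive = bool(row["wt_passes"])
            dependent = bool(row["dependent"])
            flags = ""
        else:
            responsive = False
            dependent = False
            flags = "no_expression_data"
        motif_status = ";".join(
            sorted({motif_by_region[r] for r in region_ids
                    if r in motif_by_region})) if region_ids else ""
        records.append(RegulonRecord(
            gene_id=gid, bound=bound, responsive=responsive,
            dependent=dependent,
            category=_category(bound, responsive, dependent),
            region_ids=region_ids, motif_status=motif_status, flags=flags))
    return records


def category_counts(records: Iterable[RegulonRecord]) -> pd.Series:
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return pd.Series(counts)


def regulon_report(records: Sequence[RegulonRecord],
                   annotation: Mapping[str, Mapping[str, str]] | None = None,
                   regions: Sequence[BindingRegion] = (),
                   ) -> tuple[pd.DataFrame, dict]:
    """Full per-gene evidence table plus a summary block.

    Returns ``(table, summary)`` where the summary contains category counts
    and a binding-region listing (one row per region, cross-timepoint
    union), mirroring a published-table style report.
    """
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "bound": r.bound,
            "responsive": r.responsive,
            "dependent": r.dependent,
            "category": r.category,
            "regions": ",".join(r.region_ids),
            "motif_sites": r.motif_status,
            "flags": r.flags,
        }
        if annotation and r.gene_id in annotation:
            extra = annotation[r.gene_id]
            row["homologue"] = extra.get("homologue", "")
            row["product"] = extra.get("product", "")
        rows.append(row)
    cols = ["gene_id", "bound", "responsive", "dependent", "category",
            "regions", "motif_sites", "flags"]
    if annotation:
        cols += ["homologue", "product"]
    table = pd.DataFrame(rows, columns=cols)
    summary = {
        "n_genes": len(records),
        "category_counts": category_counts(records).to_dict(),
        "n_binding_regions": len([r for r in regions
                                  if not r.present_in_control]),
        "region_listing": [
            {"region_id": r.region_id,
             "interval": f"{r.replicon}:{r.start}-{r.end}",
             "targets": ",".join(r.target_gene_ids),
             "timepoints": ",".join(sorted(r.timepoints))}
            for r in regions if not r.present_in_control],
    }
    return table, summary
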