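"""Target-gene assignment: the evidence-prioritisation ladder.

Evidence sources are ranked coding > SMR > ABC > closest gene. Coding
evidence (a credible-set coding variant, with externally supplied
deleteriousness annotations such as CADD) settles a locus outright. When
both SMR and ABC nominate genes, their intersection is the consensus
assignment; if the sets are disjoint the union is retained. If ABC is the
only source, the single highest-scoring prediction is used. A locus with
no functional evidence falls back to the closest gene at low confidence —
the only route to the low tier.
"""

from __future__ import annotations

import dataclasses

import pandas as pd


@dataclasses.dataclass
class EvidenceBundle:
    """Per-locus evidence. Gene lists may be empty; annotations optional.

    ``coding`` maps gene → annotation dict (e.g. {"cadd": 23.5});
    ``smr`` maps gene → P_SMR; ``abc`` maps gene → best ABC score;
    ``closest`` lists the nearest gene(s) (ties all reported).
    """

    locus_id: str
    coding: dict = dataclasses.field(default_factory=dict)
    smr: dict = dataclasses.field(default_factory=dict)
    abc: dict = dataclasses.field(default_factory=dict)
    closest: list = dataclasses.field(default_factory=list)
    intronic: bool = False


@dataclasses.dataclass
class GeneAssignment:
    locus_id: str
    genes: list
    sources: list
    tier: str
    intronic: bool = False


def closest_gene(lead_pos: int, lead_chrom: str, genes: pd.DataFrame):
    """Nearest gene(s) by TSS distance, plus an intronic flag.

    ``genes`` needs ``gene chrom tss`` (+optional ``start end`` gene-body
    bounds used for the intronic flag). Equidistant TSSs are all reported
    with the tie flagged.

    Returns ``(gene_list, intronic, tied)``.
    """
    same = genes[genes["chrom"].astype(str) == str(lead_chrom)]
    if same.empty:
        raise ValueError(f"no genes on chromosome {lead_chrom}")
    dist = (same["tss"] - int(lead_pos)).abs()
    dmin = dist.min()
    winners = sorted(same.loc[dist == dmin, "gene"].tolist())
    intronic = False
    if {"start", "end"}.issubset(genes.columns):
        body = same[(same["start"] <= lead_pos) & (lead_pos < same["end"])]
        intronic = not body.empty
    return winners, intronic, len(winners) > 1


def assign_target_genes(bundle: EvidenceBundle) -> GeneAssignment:
    """Resolve one locus through the evidence ladder."""
    if not (bundle.coding or bundle.smr or bundle.abc or bundle.closest):
        raise ValueError(f"locus {bundle.locus_id}: empty evidence bundle")
    if bundle.coding:
        return GeneAssignment(bundle.locus_id, sorted(bundle.coding), ["coding"], "high",
                              bundle.intronic)
    if bundle.smr and bundle.abc:
        consensus = set(bundle.smr) & set(bundle.abc)
        genes = consensus if consensus else set(bundle.smr) | set(bundle.abc)
        return GeneAssignment(bundle.locus_id, sorted(genes), ["smr", "abc"], "high",
                              bundle.intronic)
    if bundle.smr:
        return GeneAssignment(bundle.locus_id, sorted(bundle.smr), ["smr"], "high",
                              bundle.intronic)
    if bundle.abc:
        best = max(sorted(bundle.abc), key=lambda g: bundle.abc[g])
        return GeneAssignment(bundle.locus_id, [best], ["abc"], "high", bundle.intronic)
    return GeneAssignment(bundle.locus_id, sorted(set(bundle.closest)), ["closest"], "low",
                          bundle.intronic)


def summarize_assignments(assignments) -> dict:
    """Deterministic tallies over a set of locus assignments."""
    assignments = list(assignments)
    genes = set()
    for a in assignments:
        genes.update(a.genes)
    return {
        "n_loci": len(assignments),
        "n_high_confidence": sum(a.tier == "high" for a in assignments),
        "n_low_confidence": sum(a.tier == "low" for a in assignments),
        "n_distinct_genes": len(genes),
        "n_intronic": sum(bool(a.intronic) for a in assignments),
    }


def assignments_table(assignments) -> pd.DataFrame:
    rows = [
        {
            "locus": a.locus_id,
            "genes": ";".join(a.genes),
            "sources": ";".join(a.sources),
            "tier": a.tier,
            "intronic": a.intronic,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)
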