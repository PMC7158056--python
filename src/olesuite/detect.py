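"""oleABCD cluster detection: motif-screened oleA candidates verified by
homology to OleBC and OleD within a +/- 5000 bp gene neighborhood.

A genome is called positive when at least one oleA candidate (>= 1 motif
hit) has, on the same contig and overlapping the window around the oleA
gene span, homologs of both queries at E <= 1e-5. Candidates are verified
independently; the genome-level call is their OR. Hits to the oleA gene
itself never count as OleBC/OleD evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import ScoringScheme, local_align
from .genomes import GeneAnnotation, GenomeRecord, TAX_RANKS
from .motif import MotifPattern, scan_sequence

DEFAULT_WINDOW_BP = 5000
DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class NeighborHit:
    gene_id: str
    evalue: float
    distance_bp: int


@dataclass(frozen=True)
class OleClusterCall:
    genome_id: str
    oleA_gene: str
    oleBC_hit: NeighborHit | None
    oleD_hit: NeighborHit | None

    @property
    def verified(self) -> bool:
        return self.oleBC_hit is not None and self.oleD_hit is not None


def find_oleA(genome: GenomeRecord, pattern: MotifPattern) -> list[str]:
    """gene_ids whose protein carries >= 1 motif match, ordered by (contig, start)."""
    hits = [
        g for g in genome.genes
        if scan_sequence(pattern, g.protein, record_id=g.gene_id)
    ]
    hits.sort(key=lambda g: (g.contig_id, g.start))
    return [g.gene_id for g in hits]


def _boundary_gap(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Gap between closest gene boundaries; 0 when the spans overlap."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def verify_cluster(
    genome: GenomeRecord,
    oleA: str,
    queries: dict[str, str],
    window: int = DEFAULT_WINDOW_BP,
    e_cut: float = DEFAULT_EVALUE_CUTOFF,
    scheme: ScoringScheme | None = None,
) -> OleClusterCall:
    """Check one oleA candidate for OleBC and OleD homologs in its vicinity.

    ``queries`` maps {"OleBC": seq, "OleD": seq}. Neighbors are the other
    genes on the same contig whose span intersects
    [oleA.start - window, oleA.end + window); for each query the best-E
    hit with E <= e_cut is kept.
    """
    for name in ("OleBC", "OleD"):
        if not queries.get(name):
            raise ValueError(f"missing or empty query {name!r}")
    scheme = scheme or ScoringScheme()
    anchor = genome.gene(oleA)
    lo, hi = anchor.start - window, anchor.end + window
    neighbors = [
        g for g in genome.genes
        if g.gene_id != oleA and g.contig_id == anchor.contig_id
        and g.start < hi and g.end > lo
    ]
    best: dict[str, NeighborHit] = {}
    for g in neighbors:
        dist = _boundary_gap(anchor, g)
        for qname, qseq in queries.items():
            hit = local_align(qseq, g.protein, scheme)
            if hit.evalue <= e_cut:
                cur = best.get(qname)
                if cur is None or hit.evalue < cur.evalue:
                    best[qname] = NeighborHit(g.gene_id, hit.evalue, dist)
    return OleClusterCall(
        genome_id=genome.genome_id,
        oleA_gene=oleA,
        oleBC_hit=best.get("OleBC"),
        oleD_hit=best.get("OleD"),
    )


def screen(
    genomes: list[GenomeRecord],
    pattern: MotifPattern,
    queries: dict[str, str],
    window: int = DEFAULT_WINDOW_BP,
    e_cut: float = DEFAULT_EVALUE_CUTOFF,
    scheme: ScoringScheme | None = None,
) -> tuple[pd.DataFrame, dict[str, list[OleClusterCall]]]:
    """Screen genomes for verified oleABCD clusters.

    Returns a presence table (one row per genome, with taxonomy and the
    best verified call) and the per-genome list of candidate calls.
    Per-genus / per-phylum positive counts come from ``taxon_counts``.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    rows = []
    all_calls: dict[str, list[OleClusterCall]] = {}
    for genome in genomes:
        calls = [
            verify_cluster(genome, cand, queries, window, e_cut, scheme)
            for cand in find_oleA(genome, pattern)
        ]
        all_calls[genome.genome_id] = calls
        verified_calls = [c for c in calls if c.verified]
        top = verified_calls[0] if verified_calls else None
        row = {"genome_id": genome.genome_id}
        for rank in TAX_RANKS:
            row[rank] = genome.taxonomy.get(rank, "")
        row.update(
            verified=bool(verified_calls),
            oleA_gene=top.oleA_gene if top else "",
            oleBC_evalue=top.oleBC_hit.evalue if top else float("nan"),
            oleD_evalue=top.oleD_hit.evalue if top else float("nan"),
            oleBC_distance_bp=top.oleBC_hit.distance_bp if top else -1,
            oleD_distance_bp=top.oleD_hit.distance_bp if top else -1,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, all_calls


def taxon_counts(table: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Positive / total genome counts per taxon at the given rank."""
    if rank not in TAX_RANKS:
        raise ValueError(f"rank must be one of {TAX_RANKS}")
    grouped = table.groupby(rank)["verified"]
    out = grouped.agg(n_positive="sum", n_total="count").reset_index()
    out["n_positive"] = out["n_positive"].astype(int)
    return out
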