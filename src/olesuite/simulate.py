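"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (seed, parameters): one explicit
NumPy RNG stream per call, no global state, byte-identical files on
regeneration. Every dataset ships a machine-readable truth record from
which the expected output of the consuming stage can be computed.

Synthetic proteins are uniform over the 20 residues except for planted
motifs and homologies, which keeps chance motif hits rare at fixture
sizes (the expected count is computed analytically and asserted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .align import local_align
from .condensation import FattySpecies, SpecificityWeights, normalize_pool, predict
from .genomes import GeneAnnotation, GenomeRecord
from .lipids import InternalStandardSpec, classify_isomer
from .motif import AMINO_ACIDS, olea_pattern

PHYLA = ("Proteobacteria", "Actinobacteria", "Chloroflexi", "Planctomycetes", "Verrucomicrobia")

DECOY_CLASSES = ("decoy_motif", "decoy_window", "decoy_scrambled", "decoy_contig")

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def _mutate(rng: np.random.Generator, protein: str, n_subst: int,
            lo: int = 0, hi: int | None = None) -> str:
    """Substitute at n_subst distinct positions, always to a different residue."""
    hi = hi if hi is not None else len(protein)
    positions = rng.choice(np.arange(lo, hi), size=n_subst, replace=False)
    chars = list(protein)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(chars[pos], "")
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def _motif_instance(rng: np.random.Generator) -> str:
    gap = int(rng.integers(14, 19))
    return (
        "EP" + _random_protein(rng, 2)
        + "AS"[rng.integers(0, 2)]
        + _random_protein(rng, gap)
        + "D" + _random_protein(rng, 2) + "NACL"
    )


def spurious_motif_expectation(n_residues: int) -> float:
    """Expected chance motif hits in n uniform random residues (union bound)."""
    p_fixed = (1 / 20) ** 7 * (2 / 20)  # 7 literals + one 2-residue choice
    return n_residues * 5 * p_fixed  # 5 admissible gap lengths


# ---------------------------------------------------------------------------
# genome sets with planted oleABCD clusters and decoys


@dataclass
class GenomeSet:
    genomes: list[GenomeRecord]
    queries: dict[str, str]  # {"OleBC": .., "OleD": ..}
    truth: dict


def _assemble_contig(rng: np.random.Generator, contig_id: str,
                     proteins: list[tuple[str, str]], spacers: list[int]):
    """Lay proteins out left to right with given intergenic spacers.

    spacers[k] precedes gene k; a trailing spacer is appended. Strands are
    drawn randomly. Returns (contig DNA, list of GeneAnnotation).
    """
    parts = []
    genes = []
    pos = 0
    for (gene_id, protein), spacer in zip(proteins, spacers):
        parts.append(_random_dna(rng, spacer))
        pos += spacer
        cds = _back_translate(protein)
        strand = "+-"[rng.integers(0, 2)]
        dna = cds if strand == "+" else str(Seq(cds).reverse_complement())
        parts.append(dna)
        genes.append(GeneAnnotation(gene_id, contig_id, pos, pos + len(dna), strand, protein))
        pos += len(dna)
    parts.append(_random_dna(rng, 150))
    return "".join(parts), genes


def _planted_genome(rng: np.random.Generator, genome_id: str, kind: str,
                    queries: dict[str, str]) -> tuple[GenomeRecord, dict]:
    """One genome of the given kind: 'positive' or a decoy class."""
    filler1 = _random_protein(rng, int(rng.integers(200, 301)))
    filler2 = _random_protein(rng, int(rng.integers(200, 301)))
    prot = _random_protein(rng, 320)
    ins = int(rng.integers(20, 260))
    motif = _motif_instance(rng)
    olea = prot[:ins] + motif + prot[ins + len(motif):]
    if kind == "decoy_motif":
        # destroy the motif with one forbidden residue at its 'D' anchor
        i = ins + len(motif) - 7
        assert olea[i] == "D"
        olea = olea[:i] + "G" + olea[i + 1:]
    olebc = _mutate(rng, queries["OleBC"], max(1, len(queries["OleBC"]) // 20))
    oled = _mutate(rng, queries["OleD"], max(1, len(queries["OleD"]) // 20))
    if kind == "decoy_scrambled":
        oled = "".join(rng.permutation(list(queries["OleD"])))

    near, far = 200, 5500  # intergenic bp; far > the 5000 bp window
    genes_main = [("fill1", filler1), ("oleBC", olebc), ("oleA", olea), ("oleD", oled),
                  ("fill2", filler2)]
    if kind == "decoy_window":
        spacers = [far, near, far, far, near]
    elif kind == "decoy_contig":
        genes_main = [("fill1", filler1), ("oleA", olea), ("fill2", filler2)]
        spacers = [near, near, near]
    else:
        spacers = [near] * 5
    contig1, genes = _assemble_contig(rng, f"{genome_id}_c1", genes_main, spacers)
    contigs = {f"{genome_id}_c1": contig1}
    if kind == "decoy_contig":
        contig2, genes2 = _assemble_contig(
            rng, f"{genome_id}_c2", [("oleBC", olebc), ("oleD", oled)], [near, near]
        )
        contigs[f"{genome_id}_c2"] = contig2
        genes = genes + genes2
    genes = [
        GeneAnnotation(f"{genome_id}_{g.gene_id}", g.contig_id, g.start, g.end, g.strand, g.protein)
        for g in genes
    ]
    record = GenomeRecord(genome_id=genome_id, genes=genes)
    info = {
        "class": kind,
        "positive": kind == "positive",
        "oleA_gene": f"{genome_id}_oleA",
        "contigs": {cid: len(seq) for cid, seq in contigs.items()},
    }
    return record, info, contigs


def make_genome_set(
    seed: int,
    n_positive: int = 30,
    n_decoy_per_class: int = 10,
    out_dir: str | Path | None = None,
) -> GenomeSet:
    """Genomes with planted oleABCD clusters plus four decoy classes.

    Decoys: (a) motif destroyed by one forbidden residue, (b) homologs
    beyond the 5000 bp window, (c) OleD neighbor replaced by a
    residue-scrambled copy, (d) homologs on a different contig.
    """
    if n_positive < 0 or n_decoy_per_class < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    queries = {
        "OleBC": _random_protein(rng, 340),
        "OleD": _random_protein(rng, 300),
    }
    plan = [("positive", i) for i in range(n_positive)]
    for cls in DECOY_CLASSES:
        plan.extend((cls, i) for i in range(n_decoy_per_class))
    genomes, truth_genomes = [], {}
    all_contigs: dict[str, dict[str, str]] = {}
    n_residues = 0
    for idx, (kind, _) in enumerate(plan):
        genome_id = f"g{idx:03d}_{kind}"
        record, info, contigs = _planted_genome(rng, genome_id, kind, queries)
        phylum = PHYLA[idx % len(PHYLA)]
        record.taxonomy = {
            "phylum": phylum,
            "family": f"{phylum}_fam{idx % 3}",
            "genus": f"{phylum}_gen{idx % 7}",
            "species": genome_id,
        }
        info["taxonomy"] = record.taxonomy
        genomes.append(record)
        truth_genomes[genome_id] = info
        all_contigs[genome_id] = contigs
        n_residues += sum(len(g.protein) for g in record.genes)
    expected_spurious = spurious_motif_expectation(n_residues)
    # chance motif hits stay negligible at fixture scale
    assert expected_spurious < 1e-4, expected_spurious
    truth = {
        "seed": seed,
        "n_positive": n_positive,
        "n_decoy_per_class": n_decoy_per_class,
        "expected_spurious_motif_hits": expected_spurious,
        "genomes": truth_genomes,
    }
    result = GenomeSet(genomes=genomes, queries=queries, truth=truth)
    if out_dir is not None:
        _write_genome_set(result, all_contigs, Path(out_dir))
    return result


def _write_genome_set(gs: GenomeSet, all_contigs, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for genome in gs.genomes:
        contigs = all_contigs[genome.genome_id]
        records = []
        for cid, seq in contigs.items():
            rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description="synthetic contig")
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["date"] = "01-JAN-2020"
            rec.annotations["data_file_division"] = "BCT"
            for g in genome.genes:
                if g.contig_id != cid:
                    continue
                feat = SeqFeature(
                    FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                    type="CDS",
                    qualifiers={"locus_tag": [g.gene_id], "translation": [g.protein]},
                )
                rec.features.append(feat)
            records.append(rec)
        SeqIO.write(records, str(out_dir / f"{genome.genome_id}.gbk"), "genbank")
        with open(out_dir / f"{genome.genome_id}.fna", "w") as fh:
            for cid, seq in contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(out_dir / f"{genome.genome_id}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genome.genes:
                fh.write(
                    f"{g.contig_id}\tolesuite\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}\n"
                )
    with open(out_dir / "queries.faa", "w") as fh:
        for name in sorted(gs.queries):
            fh.write(f">{name}\n{gs.queries[name]}\n")
    with open(out_dir / "taxonomy.tsv", "w") as fh:
        fh.write("genome_id\tphylum\tfamily\tgenus\tspecies\n")
        for genome in gs.genomes:
            t = genome.taxonomy
            fh.write(
                f"{genome.genome_id}\t{t['phylum']}\t{t['family']}\t{t['genus']}\t{t['species']}\n"
            )
    _dump_truth(gs.truth, out_dir / "truth.json")


def _dump_truth(truth: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# protein families with controlled pairwise identities


@dataclass
class FamilySet:
    seqs: dict[str, str]
    phyla: dict[str, str]
    truth: dict


def make_family(
    seed: int,
    block_sizes: tuple[int, ...] = (5, 5),
    within_identity: float = 90.0,
    between_identity: float = 40.0,
    length: int = 150,
    out_dir: str | Path | None = None,
) -> FamilySet:
    """Sequence blocks with controlled within- and between-block identity.

    Within a block, members carry disjoint substitution sets against the
    block ancestor, so pairwise identity is (length - 2d)/length by
    construction; realized identities are re-measured with the internal
    aligner and must land within +/-2 points of the target. Between-block
    identity is approximate (ancestors diverged from a common root).
    """
    if not 0 <= between_identity < within_identity <= 100:
        raise ValueError("need 0 <= between < within <= 100")
    rng = np.random.default_rng(seed)
    d = round(length * (1 - within_identity / 100) / 2)
    margin = 3  # keep substitutions off the termini so local alignment spans fully
    for size in block_sizes:
        if d * size > length - 2 * margin:
            raise ValueError(
                f"identity target {within_identity}% infeasible for block of {size} "
                f"sequences of length {length}"
            )
    # ancestors diverge from a common root; identity ~ (1-q)^2 + q^2/19;
    # a target of 0 means unrelated blocks (independent random ancestors)
    q = 1 - np.sqrt(max(between_identity, 1.0) / 100)
    root = _random_protein(rng, length)
    seqs: dict[str, str] = {}
    phyla: dict[str, str] = {}
    expected_within = 100 * (length - 2 * d) / length
    for b, size in enumerate(block_sizes):
        if between_identity == 0:
            ancestor = _random_protein(rng, length)
        else:
            ancestor = _mutate(rng, root, round(q * length), lo=margin, hi=length - margin)
        positions = rng.permutation(np.arange(margin, length - margin))
        phylum = PHYLA[b % len(PHYLA)]
        for m in range(size):
            chars = list(ancestor)
            for pos in positions[m * d : (m + 1) * d]:
                alternatives = AMINO_ACIDS.replace(chars[pos], "")
                chars[pos] = alternatives[rng.integers(0, len(alternatives))]
            sid = f"fam{b}_m{m}"
            seqs[sid] = "".join(chars)
            phyla[sid] = phylum
    # generation-time verification against the alignment engine
    realized = []
    for b, size in enumerate(block_sizes):
        for m1 in range(size):
            for m2 in range(m1 + 1, size):
                hit = local_align(seqs[f"fam{b}_m{m1}"], seqs[f"fam{b}_m{m2}"])
                realized.append(hit.percent_identity)
    if realized and max(abs(r - within_identity) for r in realized) > 2.0:
        raise RuntimeError("realized within-block identities off target by > 2 points")
    truth = {
        "seed": seed,
        "block_sizes": list(block_sizes),
        "within_identity_target": within_identity,
        "between_identity_target": between_identity,
        "expected_within_identity": expected_within,
        "realized_within_identities": realized,
        "expected_node_count": len(block_sizes),
        "phylum_of_block": {str(b): PHYLA[b % len(PHYLA)] for b in range(len(block_sizes))},
    }
    fs = FamilySet(seqs=seqs, phyla=phyla, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "family.faa", "w") as fh:
            for sid in sorted(seqs):
                fh.write(f">{sid}\n{seqs[sid]}\n")
        with open(out / "phyla.tsv", "w") as fh:
            fh.write("id\tphylum\n")
            for sid in sorted(phyla):
                fh.write(f"{sid}\t{phyla[sid]}\n")
        _dump_truth(truth, out / "truth.json")
    return fs


# ---------------------------------------------------------------------------
# species trees with planted clustered presence


@dataclass
class TreePresence:
    newick: str
    table: pd.DataFrame
    truth: dict


def _random_join(rng: np.random.Generator, parts: list[str]) -> str:
    parts = list(parts)
    while len(parts) > 1:
        i = int(rng.integers(0, len(parts)))
        a = parts.pop(i)
        j = int(rng.integers(0, len(parts)))
        b = parts.pop(j)
        bl_a, bl_b = rng.uniform(0.05, 1.0, size=2)
        parts.append(f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})")
    return parts[0]


def make_tree_presence(
    seed: int,
    genera_spec: list[tuple[str, int]] | None = None,
    k_clusters: int = 7,
    out_dir: str | Path | None = None,
) -> TreePresence:
    """Random tree with genus-monophyletic blocks and k planted presence runs.

    Exactly ``k_clusters`` genus blocks are fully positive, chosen from
    the realized ladderized genus order so that positive blocks are
    separated by at least one negative genus; this needs
    2k - 1 <= n_genera.
    """
    if genera_spec is None:
        genera_spec = [(f"Genus{i:02d}", 3 + i % 4) for i in range(16)]
    n_genera = len(genera_spec)
    if k_clusters > n_genera:
        raise ValueError("k_clusters exceeds number of genera")
    if k_clusters > 0 and 2 * k_clusters - 1 > n_genera:
        raise ValueError("cannot separate positive genus blocks: need 2k-1 <= n_genera")
    rng = np.random.default_rng(seed)
    genus_newick = {}
    species_of = {}
    for genus, n_sp in genera_spec:
        names = [f"{genus}_sp{i}" for i in range(n_sp)]
        species_of[genus] = names
        genus_newick[genus] = (
            _random_join(rng, names) if n_sp > 1 else names[0]
        )
    newick = _random_join(rng, [genus_newick[g] for g, _ in genera_spec]) + ";"

    from . import phylo

    import io
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    order = phylo.canonical_leaf_order(tree)
    genus_order = []
    for leaf in order:
        genus = leaf.rsplit("_sp", 1)[0]
        if not genus_order or genus_order[-1] != genus:
            genus_order.append(genus)
    assert len(genus_order) == n_genera, "genus blocks are not contiguous"
    if k_clusters == 0:
        positive = set()
    elif k_clusters == 1:
        positive = {genus_order[n_genera // 2]}
    else:
        step = (n_genera - 1) / (k_clusters - 1)
        positive = {genus_order[round(i * step)] for i in range(k_clusters)}
    rows = []
    for gi, (genus, _) in enumerate(genera_spec):
        phylum = PHYLA[gi % len(PHYLA)]
        for sp in species_of[genus]:
            rows.append(
                {
                    "species_id": sp,
                    "phylum": phylum,
                    "family": f"{phylum}_family",
                    "genus": genus,
                    "present": genus in positive,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "k_clusters": k_clusters,
        "n_genera": n_genera,
        "n_species": int(table.shape[0]),
        "positive_genera": sorted(positive),
        "expected_ubiquity_rate": 1.0,
    }
    tp = TreePresence(newick=newick, table=table, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(newick + "\n")
        table.to_csv(out / "presence.tsv", sep="\t", index=False)
        _dump_truth(truth, out / "truth.json")
    return tp


# ---------------------------------------------------------------------------
# GC/MS peak tables from the condensation model


@dataclass
class PeakSet:
    peaks: pd.DataFrame
    truth: dict


_BRANCH_PAIR_OF_CLASS = {
    "isoiso": ("iso", "iso"),
    "isoai": ("iso", "anteiso"),
    "aiai": ("anteiso", "anteiso"),
    "isosc": ("iso", "straight"),
    "aisc": ("anteiso", "straight"),
    "scsc": ("straight", "straight"),
}


def make_peak_table(
    seed: int,
    pool: list[FattySpecies],
    weights: SpecificityWeights,
    n_molecules: int = 100_000,
    noise_cv: float = 0.0,
    is_spec: InternalStandardSpec | None = None,
    response_factors: dict[tuple[int, str], float] | None = None,
    out_path: str | Path | None = None,
) -> PeakSet:
    """Sample a GC/MS olefin peak table from the condensation model.

    Molecule counts per (chain length, isomer class) are multinomial over
    the model's predicted distribution; areas are counts x response
    factor x lognormal noise (unit mean, coefficient of variation
    ``noise_cv``). The internal-standard row is appended last.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    is_spec = is_spec or InternalStandardSpec("triacontane", 40.0)
    response_factors = response_factors or {}
    rows = []
    probs_out = {}
    counts_out = {}
    if n_molecules > 0:
        dist = predict(pool, weights).joint_distribution()
        counts = rng.multinomial(n_molecules, dist.to_numpy())
        if noise_cv > 0:
            sigma = float(np.sqrt(np.log(1 + noise_cv**2)))
            noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(counts))
        else:
            noise = np.ones(len(counts))
        for (key, p), cnt, eps in zip(dist.items(), counts, noise):
            chain, cls = key
            probs_out[f"{chain}|{cls}"] = float(p)
            counts_out[f"{chain}|{cls}"] = int(cnt)
            b1, b2 = _BRANCH_PAIR_OF_CLASS[cls]
            rf = response_factors.get((chain, cls), 1.0)
            rows.append(
                {
                    "analyte_class": "olefin",
                    "chain_length": int(chain),
                    "branch1": b1,
                    "branch2": b2,
                    "area": float(cnt) * rf * float(eps),
                }
            )
    rows.append(
        {
            "analyte_class": "internal_standard",
            "chain_length": 30,
            "branch1": "straight",
            "branch2": "straight",
            "area": max(1.0, n_molecules / 10.0),
        }
    )
    peaks = pd.DataFrame(rows, columns=list(("analyte_class", "chain_length", "branch1", "branch2", "area")))
    truth = {
        "seed": seed,
        "n_molecules": n_molecules,
        "noise_cv": noise_cv,
        "is_compound": is_spec.compound,
        "is_amount_ug": is_spec.amount_ug,
        "pool": [[s.chain_length, s.branch, s.abundance] for s in normalize_pool(pool)],
        "weights": {f"{c}|{b}": w for (c, b), w in sorted(weights.w.items())},
        "category_probs": probs_out,
        "category_counts": counts_out,
    }
    ps = PeakSet(peaks=peaks, truth=truth)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        peaks.to_csv(out_path, index=False)
        _dump_truth(truth, out_path.with_suffix(".truth.json"))
    return ps
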