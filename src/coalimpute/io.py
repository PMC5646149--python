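"""Readers and writers for the exchange formats.

Haplotypes travel as IMPUTE hap/legend/sample triplets or phased VCF
(1-based positions, ``|``-separated GT); genotype probabilities as
IMPUTE2-style .gen triplets; tree samples as multi-tree Newick files with
branch lengths in internal coalescent units; cohort metadata and result
tables as TSV.  All round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._tree import GeneTree
from .consensus import ConsensusTree
from .simulate import Cohort, HaplotypeMatrix

__all__ = [
    "ParseError",
    "write_hap_legend_sample",
    "read_hap_legend_sample",
    "write_phased_vcf",
    "read_phased_vcf",
    "write_gen",
    "read_gen",
    "write_trees_newick",
    "read_trees_newick",
    "write_consensus_newick",
    "write_cohort",
    "read_cohort",
]


class ParseError(ValueError):
    """Malformed record in an input file."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ----------------------------------------------------------------------
# IMPUTE hap/legend/sample
def write_hap_legend_sample(prefix, haps: HaplotypeMatrix, sample_ids=None) -> None:
    """Write ``<prefix>.hap``, ``<prefix>.legend`` and ``<prefix>.sample``.

    The .hap file holds one row per variant with one 0/1 column per
    haplotype; consecutive haplotype pairs form the samples.
    """
    prefix = Path(prefix)
    with open(f"{prefix}.legend", "w") as fh:
        fh.write("id position a0 a1\n")
        for j, pos in enumerate(haps.positions):
            fh.write(f"site_{j} {pos} A C\n")
    np.savetxt(f"{prefix}.hap", haps.alleles.T, fmt="%d", delimiter=" ")
    if sample_ids is None:
        sample_ids = [f"ind_{i}" for i in range(haps.n_haplotypes // 2)]
    with open(f"{prefix}.sample", "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0\n")


def read_hap_legend_sample(prefix) -> HaplotypeMatrix:
    prefix = Path(prefix)
    legend = pd.read_csv(f"{prefix}.legend", sep=r"\s+")
    alleles = np.loadtxt(f"{prefix}.hap", dtype=np.uint8, ndmin=2).T
    if alleles.shape[1] != len(legend):
        raise ParseError(f"{prefix}.hap", 1,
                         f"{alleles.shape[1]} variants in .hap but {len(legend)} in .legend")
    return HaplotypeMatrix(
        ids=[f"hap_{i}" for i in range(alleles.shape[0])],
        positions=legend["position"].to_numpy(),
        alleles=alleles,
    )


# ----------------------------------------------------------------------
# phased VCF
def write_phased_vcf(path, haps: HaplotypeMatrix, chrom: str = "1") -> None:
    """Write a minimal phased VCF: one diploid sample per consecutive
    haplotype pair, GT with the ``|`` phased separator."""
    n_ind = haps.n_haplotypes // 2
    if haps.n_haplotypes % 2:
        raise ValueError("phased VCF output needs an even number of haplotypes")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={int(haps.positions[-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"ind_{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j, pos in enumerate(haps.positions):
            gts = "\t".join(
                f"{haps.alleles[2 * i, j]}|{haps.alleles[2 * i + 1, j]}"
                for i in range(n_ind)
            )
            fh.write(f"{chrom}\t{pos}\tsite_{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path) -> HaplotypeMatrix:
    """Read a phased VCF into a haplotype matrix.

    Raises :class:`ParseError` (with the line number) on unphased ``/``
    genotype separators or non-biallelic records.
    """
    from cyvcf2 import VCF

    # locate the first data line for error reporting
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            header_lines += 1
            if line.startswith("#CHROM"):
                break
    positions = []
    columns = []
    vcf = VCF(str(path))
    try:
        for rec_no, rec in enumerate(vcf):
            line_no = header_lines + 1 + rec_no
            if len(rec.ALT) != 1:
                raise ParseError(path, line_no, "expected biallelic records")
            gts = rec.genotypes  # [a, b, phased]
            for g in gts:
                if len(g) != 3 or not g[2]:
                    raise ParseError(
                        path, line_no,
                        "unphased genotype separator '/': phased haplotypes required",
                    )
            positions.append(rec.POS)
            columns.append([allele for g in gts for allele in g[:2]])
    finally:
        vcf.close()
    alleles = np.array(columns, dtype=np.uint8).T
    return HaplotypeMatrix(
        ids=[f"hap_{i}" for i in range(alleles.shape[0])],
        positions=np.asarray(positions),
        alleles=alleles,
    )


# ----------------------------------------------------------------------
# IMPUTE2-style .gen probabilities
def write_gen(path, posterior, chrom: str = "1", positions=None) -> None:
    """Write genotype probability triplets, one row per imputed variant."""
    probs = posterior.probs
    with open(path, "w") as fh:
        for k, site in enumerate(posterior.masked_idx):
            pos = site if positions is None else positions[site]
            fields = [chrom, f"site_{site}", str(int(pos)), "A", "C"]
            for i in range(probs.shape[0]):
                fields.extend(f"{probs[i, k, g]:.6f}" for g in (0, 1, 2))
            fh.write(" ".join(fields) + "\n")


def read_gen(path):
    """Read a .gen file; returns (site_ids, positions, probs array)."""
    ids, positions, rows = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 8 or (len(parts) - 5) % 3:
                raise ParseError(path, line_no, "malformed .gen record")
            ids.append(parts[1])
            positions.append(int(parts[2]))
            rows.append(np.array(parts[5:], dtype=float).reshape(-1, 3))
    return ids, np.array(positions), np.stack(rows, axis=1)


# ----------------------------------------------------------------------
# Newick tree samples
def write_trees_newick(path, trees, thetas=None, alphas=None, scalars_path=None) -> None:
    """Write one Newick tree per line; optionally a TSV of per-sample
    scalars (theta, alpha) beside it."""
    if hasattr(trees, "trees"):
        sample = trees
        trees = sample.trees
        thetas = sample.thetas if thetas is None else thetas
        alphas = sample.alphas if alphas is None else alphas
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")
    if scalars_path is not None:
        cols = {"sample": np.arange(len(trees))}
        if thetas is not None:
            cols["theta"] = thetas
        if alphas is not None:
            cols["alpha"] = alphas
        pd.DataFrame(cols).to_csv(scalars_path, sep="\t", index=False)


def read_trees_newick(path) -> list[GeneTree]:
    trees = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(GeneTree.from_newick(line))
            except Exception as exc:
                raise ParseError(path, line_no, f"bad Newick record: {exc}") from exc
    return trees


def write_consensus_newick(path, consensus: ConsensusTree) -> None:
    """Write the annotated consensus: support values as internal labels,
    mean posterior times encoded as node heights."""
    tree = consensus.to_gene_tree()
    ch = tree.children()
    b = tree.branch_lengths()
    n = tree.n_leaves
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if node < n:
            s = tree.labels[node]
        else:
            s = "(" + ",".join(parts.pop(c) for c in ch[node]) + ")"
            s += f"{consensus.support[node - n]:.4g}"
        if tree.parent[node] >= 0:
            s += f":{b[node]:.10g}"
        parts[node] = s
    with open(path, "w") as fh:
        fh.write(parts[tree.root] + ";\n")


# ----------------------------------------------------------------------
# cohort directories
def write_cohort(out_dir, cohort: Cohort) -> None:
    """Write a cohort as hap/legend/sample truth plus TSV metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_hap_legend_sample(out_dir / "truth", cohort.haps)
    meta = pd.DataFrame({
        "haplotype": np.arange(cohort.haps.n_haplotypes),
        "role": [
            "study" if h in set(cohort.study_ids.tolist()) else "reference"
            for h in range(cohort.haps.n_haplotypes)
        ],
        "deme": (cohort.demes if cohort.demes is not None
                 else np.zeros(cohort.haps.n_haplotypes, dtype=int)),
    })
    pair_of = np.empty(cohort.haps.n_haplotypes, dtype=int)
    for pairs in (cohort.study_pairs, cohort.reference_pairs):
        for a, b in pairs:
            pair_of[a] = b
            pair_of[b] = a
    meta["partner"] = pair_of
    meta.to_csv(out_dir / "haplotypes.tsv", sep="\t", index=False)
    sites = pd.DataFrame({
        "site": np.arange(cohort.haps.n_sites),
        "position": cohort.haps.positions,
        "measured": np.isin(np.arange(cohort.haps.n_sites), cohort.measured_idx).astype(int),
    })
    sites.to_csv(out_dir / "sites.tsv", sep="\t", index=False)


def read_cohort(out_dir) -> Cohort:
    out_dir = Path(out_dir)
    haps = read_hap_legend_sample(out_dir / "truth")
    meta = pd.read_csv(out_dir / "haplotypes.tsv", sep="\t")
    sites = pd.read_csv(out_dir / "sites.tsv", sep="\t")
    study_ids = meta.loc[meta["role"] == "study", "haplotype"].to_numpy()
    ref_ids = meta.loc[meta["role"] == "reference", "haplotype"].to_numpy()

    def pairs_for(ids):
        ids_set = set(ids.tolist())
        done, out = set(), []
        for h in ids:
            if h in done:
                continue
            partner = int(meta.loc[meta["haplotype"] == h, "partner"].iloc[0])
            if partner not in ids_set:
                raise ParseError(out_dir / "haplotypes.tsv", int(h) + 2,
                                 "diploid partner crosses the study/reference split")
            out.append((h, partner))
            done.update((h, partner))
        return np.array(out, dtype=int)

    measured = sites.loc[sites["measured"] == 1, "site"].to_numpy()
    masked = sites.loc[sites["measured"] == 0, "site"].to_numpy()
    demes = meta["deme"].to_numpy()
    return Cohort(
        haps=haps,
        study_ids=np.sort(study_ids),
        reference_ids=np.sort(ref_ids),
        study_pairs=pairs_for(study_ids),
        reference_pairs=pairs_for(ref_ids),
        measured_idx=measured,
        masked_idx=masked,
        demes=demes if demes.any() else None,
    )
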