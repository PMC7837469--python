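"""Readers/writers for the interchange formats and run manifests.

All tabular formats are TSV with a header row.  Coordinates are 1-based
inclusive on disk (GFF3 convention) and 0-based half-open in memory.

Formats:

* panel TSV: ``snp_id  chrom  pos  ref  alt  <line...>`` with one 0/1
  allele column per sequenced reference line (0 = ref base).
* haplotype TSV: ``hap  Q  alleles`` with the collapsed haplotype's
  frequency and its 0/1 allele string.
* observations TSV: ``plant_id  set_id  read_id  snp_id  allele`` — one row
  per scored SNP per read-pair.
* family TSV: ``family_id  year  maternal_plant  cohort  offspring_plant
  cross`` with cross in {O, S, NA}; single-plant families use NA offspring.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import ReadPairObservation
from .models import Family
from .panel import GeneModel, HaplotypePanel, PanelSNP, extract_haplotypes

__all__ = [
    "read_gff3_genes",
    "read_panel_tsv",
    "write_panel_tsv",
    "write_haplotypes_tsv",
    "read_observations_tsv",
    "write_observations_tsv",
    "read_family_tsv",
    "write_family_tsv",
    "write_results_tsv",
    "write_manifest",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_gff3_genes(path: str | Path, featuretype: str = "gene") -> list[GeneModel]:
    """Gene models from GFF3, converted to 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for f in db.features_of_type(featuretype):
        genes.append(
            GeneModel(
                gene_id=f.id,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
            )
        )
    return genes


def write_panel_tsv(
    path: str | Path,
    line_ids: list[str],
    line_alleles: np.ndarray,
    snps: list[PanelSNP],
    chrom: str = "chr1",
) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": chrom,
            "pos": [s.pos + 1 for s in snps],  # 1-based on disk
            "ref": [s.ref_base for s in snps],
            "alt": [s.alt_base for s in snps],
        }
    )
    for i, lid in enumerate(line_ids):
        df[lid] = line_alleles[i, :]
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path, set_id: str = "gs00000") -> HaplotypePanel:
    """Read a line-level SNP table and collapse it into a haplotype panel."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["snp_id", "chrom", "pos", "ref", "alt"], path)
    meta = ["snp_id", "chrom", "pos", "ref", "alt"]
    line_ids = [c for c in df.columns if c not in meta]
    if not line_ids:
        raise ValueError(f"{path}: no reference-line allele columns found")
    alleles = df[line_ids].to_numpy().T  # (lines, SNPs)
    snps = [
        PanelSNP(r.snp_id, int(r.pos) - 1, r.ref, r.alt, delta=None, p_panel=np.nan)
        for r in df.itertuples(index=False)
    ]
    return extract_haplotypes(alleles, line_ids=line_ids, set_id=set_id, snps=snps)


def write_haplotypes_tsv(path: str | Path, panel: HaplotypePanel) -> None:
    rows = [
        {"hap": k, "Q": panel.Q[k], "alleles": "".join(map(str, panel.alleles[k]))}
        for k in range(panel.K)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_observations_tsv(
    path: str | Path, reads: list[ReadPairObservation], snp_ids: list[str] | None = None
) -> None:
    rows = []
    for r in reads:
        for idx, allele in zip(r.snp_indices, r.alleles):
            rows.append(
                {
                    "plant_id": r.plant_id,
                    "set_id": r.set_id,
                    "read_id": r.read_id,
                    "snp_id": snp_ids[idx] if snp_ids else f"snp{idx}",
                    "allele": int(allele),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observations_tsv(
    path: str | Path, snp_index: dict[str, int] | None = None
) -> list[ReadPairObservation]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["plant_id", "set_id", "read_id", "snp_id", "allele"], path)
    reads = []
    for (plant, set_id, read_id), grp in df.groupby(
        ["plant_id", "set_id", "read_id"], sort=False
    ):
        if snp_index is not None:
            idx = np.array([snp_index[s] for s in grp["snp_id"]], dtype=np.intp)
        else:
            idx = grp["snp_id"].str.replace("snp", "", regex=False).astype(int).to_numpy()
        reads.append(
            ReadPairObservation(
                plant_id=str(plant),
                set_id=str(set_id),
                read_id=str(read_id),
                snp_indices=idx,
                alleles=grp["allele"].to_numpy(),
            )
        )
    return reads


def write_family_tsv(path: str | Path, families: list[Family]) -> None:
    rows = []
    for f in families:
        if not f.offspring:
            rows.append(
                {"family_id": f.family_id, "year": f.year, "maternal_plant": f.maternal_plant,
                 "cohort": f.cohort, "offspring_plant": "NA", "cross": "NA"}
            )
        for pid, cross in f.offspring:
            rows.append(
                {"family_id": f.family_id, "year": f.year, "maternal_plant": f.maternal_plant,
                 "cohort": f.cohort, "offspring_plant": pid, "cross": cross}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_family_tsv(path: str | Path) -> list[Family]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(
        df, ["family_id", "year", "maternal_plant", "cohort", "offspring_plant", "cross"], path
    )
    fams = []
    for fid, grp in df.groupby("family_id", sort=False):
        first = grp.iloc[0]
        offspring = [
            (str(r.offspring_plant), r.cross if r.cross in ("O", "S") else "O")
            for r in grp.itertuples(index=False)
            if str(r.offspring_plant) not in ("NA", "", "nan")
        ]
        fams.append(
            Family(
                family_id=str(fid),
                year=int(first["year"]),
                maternal_plant=str(first["maternal_plant"]),
                cohort=str(first["cohort"]),
                offspring=offspring,
            )
        )
    return fams


def write_results_tsv(path: str | Path, results: pd.DataFrame) -> None:
    """Results table with p/q-values serialized in 6-significant-digit scientific form."""
    df = results.copy()
    for c in df.columns:
        if c.startswith(("p_value", "q_value")):
            df[c] = df[c].map(lambda v: f"{v:.6e}" if pd.notna(v) else "NA")
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, inputs: list[str], config: dict, seed: int | None) -> None:
    """Reproducibility manifest: inputs with content hashes, config, seed, version."""
    from . import __version__

    entries = []
    for p in inputs:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        entries.append({"path": str(p), "sha256": digest})
    manifest = {
        "inputs": entries,
        "config": config,
        "seed": seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
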