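"""Plain-text interchange: TSV tables and VCF genotypes.

All tabular artifacts are tab-separated with fixed column contracts (see the
writer docstrings). Genotypes travel either as a dosage TSV (snp x sample)
with a sidecar coordinate table, or as a VCF with a ``DS`` FORMAT field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CellReference
from .mr import Genotypes
from .qc import IntensityData


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, inputs: dict, seed, extra: dict | None = None) -> Path:
    """JSON sidecar: input checksums, seed and package version."""
    from . import __version__

    payload = {
        "inputs": {k: file_checksum(v) if Path(str(v)).exists() else str(v)
                   for k, v in inputs.items()},
        "seed": seed,
        "version": __version__,
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---- intensities ---------------------------------------------------------

def write_intensities(data: IntensityData, outdir, prefix: str = "") -> dict:
    """Long intensity table (probe_id, sample_id, M, U, beadcount) plus
    control-probe table and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = (
        data.M.stack().rename("M").to_frame()
        .join(data.U.stack().rename("U"))
        .join(data.beadcount.stack().rename("beadcount"))
        .reset_index()
    )
    long.columns = ["probe_id", "sample_id", "M", "U", "beadcount"]
    paths = {
        "intensities": write_tsv(long, outdir / f"{prefix}intensities.tsv"),
        "controls": write_tsv(data.controls.reset_index(names="control_id"),
                              outdir / f"{prefix}controls.tsv"),
        "manifest": write_tsv(data.manifest.reset_index(),
                              outdir / f"{prefix}manifest.tsv"),
    }
    return paths


def read_intensities(outdir, prefix: str = "") -> IntensityData:
    outdir = Path(outdir)
    long = pd.read_csv(outdir / f"{prefix}intensities.tsv", sep="\t")
    M = long.pivot(index="probe_id", columns="sample_id", values="M")
    U = long.pivot(index="probe_id", columns="sample_id", values="U")
    bead = long.pivot(index="probe_id", columns="sample_id", values="beadcount")
    controls = pd.read_csv(outdir / f"{prefix}controls.tsv", sep="\t") \
        .set_index("control_id")
    manifest = pd.read_csv(outdir / f"{prefix}manifest.tsv", sep="\t",
                           dtype={"chr": str}).set_index("probe_id")
    manifest = manifest.loc[M.index]
    return IntensityData(M=M, U=U, beadcount=bead, controls=controls,
                         manifest=manifest)


# ---- genotypes -----------------------------------------------------------

def write_genotypes_tsv(gt: Genotypes, outdir, prefix: str = "") -> dict:
    outdir = Path(outdir)
    return {
        "dosages": write_tsv(gt.dosages.reset_index(names="snp"),
                             outdir / f"{prefix}dosages.tsv"),
        "snp_coords": write_tsv(gt.coords.reset_index(),
                                outdir / f"{prefix}snp_coords.tsv"),
    }


def read_genotypes_tsv(outdir, prefix: str = "") -> Genotypes:
    outdir = Path(outdir)
    dos = pd.read_csv(outdir / f"{prefix}dosages.tsv", sep="\t").set_index("snp")
    coords = pd.read_csv(outdir / f"{prefix}snp_coords.tsv", sep="\t",
                         dtype={"chr": str}).set_index("snp")
    return Genotypes(dosages=dos, coords=coords)


def write_genotypes_vcf(gt: Genotypes, path) -> Path:
    """Minimal VCF 4.2 with per-sample DS (dosage) genotype field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(gt.dosages.columns)
    coords = gt.coords
    order = coords.assign(_chr=coords["chr"].astype(str),
                          _pos=coords["pos"].astype(int)) \
        .sort_values(["_chr", "_pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        for c in sorted(coords["chr"].astype(str).unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in order:
            row = coords.loc[snp]
            ds = gt.dosages.loc[snp, samples]
            fields = [str(row["chr"]), str(int(row["pos"])), str(snp),
                      str(row.get("other_allele", "G")),
                      str(row.get("effect_allele", "A")),
                      ".", "PASS", ".", "DS"]
            fields += [f"{v:.3f}" if np.isfinite(v) else "." for v in ds]
            fh.write("\t".join(fields) + "\n")
    return path


def read_genotypes_vcf(path) -> Genotypes:
    """Read a dosage VCF (DS field required; ALT is the effect allele)."""
    path = Path(path)
    samples, rows, dosage_rows = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            fmt = parts[8].split(":")
            if "DS" not in fmt:
                raise ValueError(
                    f"VCF record {parts[2]} lacks a DS FORMAT field; "
                    "re-export dosages with DS")
            k = fmt.index("DS")
            vals = [p.split(":")[k] for p in parts[9:]]
            dosage_rows.append([float(v) if v != "." else np.nan for v in vals])
            rows.append({"snp": parts[2], "chr": parts[0], "pos": int(parts[1]),
                         "effect_allele": parts[4], "other_allele": parts[3]})
    if samples is None:
        raise ValueError("VCF has no #CHROM header line")
    coords = pd.DataFrame(rows).set_index("snp")
    dosages = pd.DataFrame(dosage_rows, index=coords.index, columns=samples)
    return Genotypes(dosages=dosages, coords=coords)


# ---- bundle --------------------------------------------------------------

def write_bundle(bundle, outdir) -> dict:
    """Write every component of a synthetic study bundle as TSV/VCF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for visit, data in bundle.intensities.items():
        paths.update({f"{visit}_{k}": v for k, v in
                      write_intensities(data, outdir, prefix=f"{visit}_").items()})
    paths["sample_sheet"] = write_tsv(bundle.phenotypes, outdir / "sample_sheet.tsv")
    paths.update(write_genotypes_tsv(bundle.genotypes, outdir))
    paths["genotypes_vcf"] = write_genotypes_vcf(bundle.genotypes,
                                                 outdir / "genotypes.vcf")
    paths["sumstats"] = write_tsv(bundle.sumstats, outdir / "gwas_sumstats.tsv")
    paths["expression"] = write_tsv(bundle.expression.reset_index(names="transcript_id"),
                                    outdir / "expression.tsv")
    paths["transcript_coords"] = write_tsv(bundle.transcript_coords,
                                           outdir / "transcript_coords.tsv")
    for visit, bio in bundle.biomarkers.items():
        paths[f"biomarkers_{visit}"] = write_tsv(
            bio.reset_index(names="sample_id"), outdir / f"biomarkers_{visit}.tsv")
    paths["cell_reference"] = write_tsv(
        bundle.cell_reference.profiles.reset_index(names="probe_id"),
        outdir / "cell_reference.tsv")
    for name, tab in bundle.truth.items():
        if isinstance(tab, pd.DataFrame):
            paths[f"truth_{name}"] = write_tsv(tab.reset_index(),
                                               outdir / f"truth_{name}.tsv")
    paths["seed_log"] = Path(outdir / "seeds.json")
    paths["seed_log"].write_text(json.dumps({"seed": bundle.config.seed}) + "\n")
    return paths


def read_cell_reference(path) -> CellReference:
    df = pd.read_csv(path, sep="\t").set_index("probe_id")
    return CellReference(profiles=df)
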