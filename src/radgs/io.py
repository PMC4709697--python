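"""Readers/writers for the pipeline's file formats.

Genotypes travel as VCF (diploid GT, 1-based positions) or as a simple
TSV dialect: individuals in rows, markers in columns, a header row of
marker ids, ``NA`` for missing.  Dosages count copies of the alternate
allele (0/1/2 for AA/AB/BB).  Pedigrees are CSV (id, sire, dam, family,
generation; -1 for unknown parents); phenotypes are TSV with an ``id``
column.  Tag intervals export as BED (0-based half-open).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import BASES, ValidationError


def read_genotypes(path, fmt: str | None = None):
    """Load a genotype matrix.

    Returns (X, sample_ids, locus_info) with X individuals x markers,
    NaN for missing.  ``fmt`` in {"vcf", "tsv"}; inferred from the
    extension by default.  Multi-allelic VCF records are skipped with a
    warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols, info = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic site {var.CHROM}:{var.POS}")
            continue
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        cols.append(gt)
        info.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0],
                     var.ID or f"{var.CHROM}:{var.POS}"))
    X = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    locus_info = pd.DataFrame(info, columns=["chrom", "pos", "ref", "alt", "id"])
    return X, samples, locus_info


def _read_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    X = df.to_numpy(dtype=float)
    ok = np.isnan(X) | np.isin(X, [0.0, 1.0, 2.0])
    if not ok.all():
        raise ValidationError("TSV genotypes must be 0/1/2 or NA")
    locus_info = pd.DataFrame({"id": df.columns})
    return X, list(df.index.astype(str)), locus_info


def write_genotypes_tsv(path, X, sample_ids, marker_ids) -> None:
    df = pd.DataFrame(np.asarray(X), index=sample_ids, columns=marker_ids)
    df.to_csv(path, sep="\t", na_rep="NA")


def write_genotypes_vcf(path, X, sample_ids, locus_info) -> None:
    """Write dosages as diploid unphased GT records.

    ``locus_info`` needs chrom and pos (0-based); ref/alt default to A/C.
    Dosage 1 becomes 0/1, 2 becomes 1/1, NaN becomes ./. .
    """
    X = np.asarray(X, dtype=float)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=radgs\n")
        chroms = pd.unique(locus_info["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for j in range(X.shape[1]):
            row = locus_info.iloc[j]
            ref = row.get("ref", "A")
            alt = row.get("alt", "C")
            if not isinstance(ref, str):
                ref = BASES[int(ref)]
            if not isinstance(alt, str):
                alt = BASES[int(alt)]
            vid = row.get("id", f"m{j}")
            calls = "\t".join(
                "./." if np.isnan(v) else gt_map[int(v)] for v in X[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{vid}\t{ref}\t"
                     f"{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValidationError("phenotype TSV needs an 'id' column")
    return df


def write_phenotypes(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"id", "sire", "dam"}
    if not need <= set(df.columns):
        raise ValidationError("pedigree CSV needs id, sire, dam columns")
    return df


def write_pedigree(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and manifests

_SCHEMA = {
    "scenario": str,
    "n_replicates": int,
    "h2": list,
    "methods": list,
    "panels": list,
    "n_families": list,
    "cv": {"n_folds": int, "n_repeats": int},
    "mcmc": {"niter": int, "burnin": int},
    "sizes": dict,
    "seed": int,
    "over_generation": bool,
    "dominance_share": float,
}


def _check_schema(cfg, schema, prefix=""):
    for key, val in cfg.items():
        if key not in schema:
            raise ValidationError(f"unknown config key {prefix + key!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                raise ValidationError(f"{prefix + key!r} must be a mapping")
            _check_schema(val, expect, prefix=f"{prefix}{key}.")
        elif expect in (int, float):
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ValidationError(f"{prefix + key!r} must be numeric")
        elif not isinstance(val, expect):
            raise ValidationError(
                f"{prefix + key!r} must be of type {expect.__name__}")


def load_config(path) -> dict:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    _check_schema(cfg, _SCHEMA)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_manifest(path, cfg: dict, seed: int, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": config_hash(cfg),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def save_fit(fit, prefix, marker_ids=None) -> None:
    """Serialize a fitted estimator: effects TSV + JSON metadata."""
    prefix = Path(prefix)
    g = getattr(fit, "marker_effects_", None)
    if g is not None:
        ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(len(g))]
        df = pd.DataFrame({"marker": ids, "effect": g})
        pip = getattr(fit, "posterior_inclusion_", None)
        if pip is not None:
            df["posterior_inclusion"] = pip
        df.to_csv(prefix.with_suffix(".effects.tsv"), sep="\t", index=False)
    meta = {
        "method": type(fit).__name__,
        "params": fit.get_params(),
        "mu": getattr(fit, "mu_", None),
        "varcomp": getattr(fit, "varcomp_", None),
        "sigma_e2": getattr(fit, "sigma_e2_", None),
        "diagnostics": getattr(fit, "diagnostics_", None),
    }
    meta["params"] = {k: (None if isinstance(v, pd.DataFrame) else v)
                      for k, v in meta["params"].items()}
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
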