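"""Readers and writers: genotype/phenotype tables, VCF, model documents.

Genotype TSV dialect: samples in rows, variants in columns, first column
the sample ID, header row of variant IDs, values in {0, 1, 2, NA}.
Phenotype TSV: two columns (sample ID, status), status 1 = case and
0 = control. Fitted models serialize to a versioned JSON document whose
write -> read -> write round trip is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    CrocpredError,
    GenotypeDataset,
    InvalidArgumentError,
    LRTable,
    MISSING,
    UnsupportedRecordError,
)
from .croc import CollapsingPlan
from .froc import RiskModel, SelectionStep, SelectionTrace

logger = logging.getLogger("crocpred")

FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------


def read_phenotype_tsv(path) -> pd.Series:
    """Two-column sample/status table; returns status indexed by sample ID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise InvalidArgumentError(
            f"phenotype file must have exactly 2 columns, got {df.shape[1]}"
        )
    status = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if status.isna().any() or not status.isin((0, 1)).all():
        bad = df.iloc[:, 1][~status.isin((0, 1)) | status.isna()].tolist()
        raise InvalidArgumentError(
            f"phenotype status must be 0 (control) or 1 (case); got {bad[:5]}"
        )
    if df.iloc[:, 0].duplicated().any():
        dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
        raise InvalidArgumentError(f"duplicate sample IDs in phenotype: {dupes[:5]}")
    return pd.Series(status.astype(int).values, index=df.iloc[:, 0].values)


def _read_genotype_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    variant_ids = [str(v) for v in df.columns]
    values = df.to_numpy()
    geno = np.full(values.shape, MISSING, dtype=np.int8)
    known = {"0": 0, "1": 1, "2": 2}
    for code, val in known.items():
        geno[values == code] = val
    unknown = ~np.isin(values, list(known) + ["NA"]) & ~pd.isna(values)
    if unknown.any():
        bad = np.unique(values[unknown])
        raise InvalidArgumentError(
            f"genotype TSV values must be 0/1/2/NA; got {bad.tolist()[:5]}"
        )
    return geno, sample_ids, variant_ids


def _read_vcf(path) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            raise UnsupportedRecordError(
                f"multiallelic or invariant site at {v.CHROM}:{v.POS} "
                f"(ALT={v.ALT}); split or drop it first"
            )
        counts = gt_map[np.asarray(v.gt_types)]
        observed = counts != MISSING
        if observed.any():
            alt_freq = counts[observed].sum() / (2.0 * observed.sum())
            if alt_freq > 0.5:
                # orient to the minor allele, which here is REF
                logger.warning(
                    "ALT is the major allele at %s:%s; flipping orientation",
                    v.CHROM, v.POS,
                )
                counts = np.where(observed, 2 - counts, MISSING).astype(np.int8)
        variant_ids.append(
            v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}"
        )
        columns.append(counts)
    if not columns:
        raise InvalidArgumentError(f"no usable variant records in {path}")
    return np.column_stack(columns), sample_ids, variant_ids


def read_genotypes(
    genotype_path,
    phenotype_path,
    fmt: str = "tsv",
    missing_policy: str = "impute",
) -> GenotypeDataset:
    """Load a genotype matrix plus phenotype and align samples by ID.

    ``missing_policy`` is either ``"impute"`` (missing genotypes become the
    major homozygote, 0) or ``"category"`` (kept as the missing sentinel and
    treated as their own genotype level downstream).
    """
    if fmt == "tsv":
        geno, sample_ids, variant_ids = _read_genotype_tsv(genotype_path)
    elif fmt == "vcf":
        geno, sample_ids, variant_ids = _read_vcf(genotype_path)
    else:
        raise InvalidArgumentError(f"unknown genotype format: {fmt}")
    status = read_phenotype_tsv(phenotype_path)

    geno_set, phen_set = set(sample_ids), set(status.index)
    only_phen = sorted(phen_set - geno_set)
    only_geno = sorted(geno_set - phen_set)
    if only_phen or only_geno:
        parts = []
        if only_phen:
            parts.append(f"in phenotype only: {only_phen[:10]}")
        if only_geno:
            parts.append(f"in genotypes only: {only_geno[:10]}")
        raise AlignmentError("sample IDs do not align; " + "; ".join(parts))

    phenotype = status.loc[sample_ids].to_numpy()
    if missing_policy == "impute":
        geno = np.where(geno == MISSING, 0, geno).astype(np.int8)
    elif missing_policy != "category":
        raise InvalidArgumentError(f"unknown missing_policy: {missing_policy}")
    return GenotypeDataset(
        genotypes=geno,
        phenotype=phenotype,
        variant_ids=variant_ids,
        sample_ids=sample_ids,
    )


def write_genotype_tsv(data: GenotypeDataset, path) -> None:
    samples = data.sample_ids or [f"S{i + 1}" for i in range(data.n_individuals)]
    df = pd.DataFrame(
        data.genotypes.astype(object), index=samples, columns=data.variant_ids
    )
    df[data.genotypes == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_phenotype_tsv(data: GenotypeDataset, path) -> None:
    samples = data.sample_ids or [f"S{i + 1}" for i in range(data.n_individuals)]
    pd.DataFrame({"sample_id": samples, "status": data.phenotype}).to_csv(
        path, sep="\t", index=False
    )


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Model documents
# ---------------------------------------------------------------------------


def model_to_document(model: RiskModel, provenance: dict | None = None) -> dict:
    t = model.lr_table
    doc = {
        "format_version": FORMAT_VERSION,
        "loci": list(model.loci),
        "lr_table": {
            "loci": list(t.loci_ids),
            "pseudocount": t.pseudocount,
            "lr_cap": t.lr_cap,
            "n_cases": t.n_cases,
            "n_controls": t.n_controls,
            "entries": [
                {
                    "genotype": [int(x) for x in row],
                    "case_count": int(a),
                    "control_count": int(b),
                    "lr": float(v),
                }
                for row, a, b, v in zip(
                    t.groups, t.case_counts, t.control_counts, t.lr
                )
            ],
        },
        "trace": {
            "chosen_size": model.trace.chosen_size,
            "steps": [
                {
                    "locus_id": s.locus_id,
                    "training_auc": s.training_auc,
                    "cv_auc": s.cv_auc,
                }
                for s in model.trace.steps
            ],
        },
        "collapsing": None,
        "config": dict(sorted(model.config.items())),
        "provenance": provenance,
    }
    plan = model.collapsing_plan
    if plan is not None:
        doc["collapsing"] = {
            "maf_threshold": plan.maf_threshold,
            "coding": plan.coding,
            "groups": [
                {"id": gid, "variants": list(vids), "auc": float(auc)}
                for gid, vids, auc in zip(
                    plan.group_ids, plan.group_variant_ids, plan.per_group_auc
                )
            ],
        }
    return doc


def document_to_model(doc: dict) -> RiskModel:
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise CrocpredError(
            f"unsupported model format version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )
    td = doc["lr_table"]
    entries = td["entries"]
    k = len(td["loci"])
    table = LRTable(
        loci_ids=tuple(td["loci"]),
        groups=np.array(
            [e["genotype"] for e in entries], dtype=np.int8
        ).reshape(len(entries), k),
        case_counts=np.array([e["case_count"] for e in entries]),
        control_counts=np.array([e["control_count"] for e in entries]),
        lr=np.array([e["lr"] for e in entries], dtype=float),
        pseudocount=td["pseudocount"],
        lr_cap=td["lr_cap"],
        n_cases=td["n_cases"],
        n_controls=td["n_controls"],
    )
    trace = SelectionTrace(
        steps=[
            SelectionStep(
                locus=-1,
                locus_id=s["locus_id"],
                training_auc=s["training_auc"],
                cv_auc=s["cv_auc"],
            )
            for s in doc["trace"]["steps"]
        ],
        chosen_size=doc["trace"]["chosen_size"],
    )
    plan = None
    if doc.get("collapsing") is not None:
        c = doc["collapsing"]
        plan = CollapsingPlan(
            group_variant_ids=[g["variants"] for g in c["groups"]],
            group_ids=[g["id"] for g in c["groups"]],
            per_group_auc=[g["auc"] for g in c["groups"]],
            maf_threshold=c["maf_threshold"],
            coding=c["coding"],
            groups=None,
        )
    return RiskModel(
        loci=list(doc["loci"]),
        lr_table=table,
        trace=trace,
        config=dict(doc["config"]),
        collapsing_plan=plan,
    )


def dumps_document(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_model(model: RiskModel, path, provenance: dict | None = None) -> None:
    Path(path).write_text(dumps_document(model_to_document(model, provenance)))


def read_model(path) -> RiskModel:
    return document_to_model(json.loads(Path(path).read_text()))
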