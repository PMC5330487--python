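"""Readers and writers for the interchange formats.

Tab-separated tables are the primary interchange format: ancestry and
genotype dosage matrices (individuals x markers, with a sidecar marker
map), per-haplotype ancestry call files, phenotype/covariate tables and
summary statistics. A minimal VCF writer emits hard calls; VCF reading
(DS field preferred, GT fallback) goes through cyvcf2.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancestry import AncestryMatrix
from .assoc import DosageMatrix

logger = logging.getLogger("admixscan.io")

#: Default legend for per-haplotype call files (RFMix-style integer codes).
DEFAULT_LEGEND = {1: "NAM", 2: "EUR", 3: "AFR"}
_CODE_OF = {"NAM": 0, "EUR": 1, "AFR": 2}

MARKER_COLUMNS = ["marker", "chrom", "pos"]


def _with_ext(prefix, ext: str) -> Path:
    """Append an extension to a path prefix without touching its stem."""
    return Path(str(prefix) + ext)


# ---------------------------------------------------------------------------
# marker maps and dosage-style matrices

def write_marker_map(path: str | Path, markers: pd.DataFrame) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map {path} lacks required columns {missing}")
    return markers


def _write_matrix_tsv(path: str | Path, ids: np.ndarray, markers: pd.DataFrame, values: np.ndarray, fmt: str) -> None:
    df = pd.DataFrame(values, columns=markers["marker"].tolist())
    df.insert(0, "iid", ids)
    df.to_csv(path, sep="\t", index=False, float_format=fmt)


def write_ancestry_tsv(prefix: str | Path, ancestry: AncestryMatrix) -> None:
    """Write NAM (and any companion) dosage matrices plus the marker map.

    Produces ``<prefix>.nam.tsv`` (+ ``.eur.tsv``/``.afr.tsv`` when
    present) and ``<prefix>.markers.tsv``.
    """
    prefix = Path(prefix)
    write_marker_map(_with_ext(prefix, ".markers.tsv"), ancestry.markers)
    _write_matrix_tsv(_with_ext(prefix, ".nam.tsv"), ancestry.ids, ancestry.markers, ancestry.nam, "%d")
    for name, mat in (("eur", ancestry.eur), ("afr", ancestry.afr)):
        if mat is not None:
            _write_matrix_tsv(_with_ext(prefix, f".{name}.tsv"), ancestry.ids, ancestry.markers, mat, "%d")


def read_ancestry_tsv(prefix: str | Path) -> AncestryMatrix:
    prefix = Path(prefix)
    markers = read_marker_map(_with_ext(prefix, ".markers.tsv"))
    nam_df = pd.read_csv(_with_ext(prefix, ".nam.tsv"), sep="\t", dtype={"iid": str})
    ids = nam_df["iid"].to_numpy()
    nam = nam_df.drop(columns="iid").to_numpy(dtype=np.int8)
    companions = {}
    for name in ("eur", "afr"):
        p = _with_ext(prefix, f".{name}.tsv")
        if p.exists():
            companions[name] = (
                pd.read_csv(p, sep="\t", dtype={"iid": str}).drop(columns="iid").to_numpy(dtype=np.int8)
            )
    return AncestryMatrix(ids=ids, markers=markers, nam=nam,
                          eur=companions.get("eur"), afr=companions.get("afr"))


def write_dosage_tsv(prefix: str | Path, dosages: DosageMatrix) -> None:
    prefix = Path(prefix)
    write_marker_map(_with_ext(prefix, ".markers.tsv"), dosages.markers)
    _write_matrix_tsv(_with_ext(prefix, ".dosage.tsv"), dosages.ids, dosages.markers, dosages.dosage, "%.6g")


def read_dosage_tsv(prefix: str | Path) -> DosageMatrix:
    prefix = Path(prefix)
    markers = read_marker_map(_with_ext(prefix, ".markers.tsv"))
    df = pd.read_csv(_with_ext(prefix, ".dosage.tsv"), sep="\t", dtype={"iid": str})
    return DosageMatrix(
        ids=df["iid"].to_numpy(), markers=markers, dosage=df.drop(columns="iid").to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# per-haplotype (RFMix-style) ancestry calls

def write_rfmix_calls(
    path: str | Path, ancestry: AncestryMatrix, legend: dict[int, str] = DEFAULT_LEGEND
) -> None:
    """Write per-haplotype ancestry codes: marker rows, two columns per individual."""
    if ancestry.haplotypes is None:
        raise ValueError("per-haplotype truth not available on this matrix")
    inv = {_CODE_OF[name]: code for code, name in legend.items()}
    cols = {}
    for i, iid in enumerate(ancestry.ids):
        for h in (0, 1):
            cols[f"{iid}.{h}"] = [inv[int(c)] for c in ancestry.haplotypes[i, h]]
    out = pd.concat([ancestry.markers[MARKER_COLUMNS].reset_index(drop=True), pd.DataFrame(cols)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_local_ancestry(
    path: str | Path,
    dialect: str = "dosage_tsv",
    legend: dict[int, str] = DEFAULT_LEGEND,
) -> AncestryMatrix:
    """Read local-ancestry calls and collapse them to NAM copy counts.

    ``dialect='dosage_tsv'`` expects the ``<prefix>.nam.tsv`` layout of
    :func:`write_ancestry_tsv` (pass the prefix); ``'rfmix_calls'``
    expects a per-haplotype call file whose integer codes are mapped
    through ``legend``. Unknown codes raise with the offending line; an
    odd haplotype column count raises.
    """
    if dialect == "dosage_tsv":
        return read_ancestry_tsv(path)
    if dialect != "rfmix_calls":
        raise ValueError(f"unknown local-ancestry dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    hap_cols = [c for c in df.columns if c not in MARKER_COLUMNS and c != "cm"]
    if len(hap_cols) % 2 != 0:
        raise ValueError(f"{path}: odd number of haplotype columns ({len(hap_cols)})")
    ids = []
    for c in hap_cols[0::2]:
        if not c.endswith(".0"):
            raise ValueError(f"{path}: haplotype column {c!r} does not follow '<iid>.0/<iid>.1'")
        ids.append(c[:-2])
    codes = df[hap_cols].to_numpy()
    known = set(legend)
    bad = ~np.isin(codes, list(known))
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: unknown ancestry code {codes[row, col]!r} at line {row + 2}, "
            f"column {hap_cols[col]!r} (legend: {legend})"
        )
    name_by_code = {code: _CODE_OF[name] for code, name in legend.items()}
    mapped = np.vectorize(name_by_code.get)(codes)  # (M, 2n) internal codes
    M, H = mapped.shape
    hap = mapped.T.reshape(H // 2, 2, M).astype(np.int8)
    nam = (hap == 0).sum(axis=1).astype(np.int8)
    eur = (hap == 1).sum(axis=1).astype(np.int8)
    afr = (hap == 2).sum(axis=1).astype(np.int8)
    markers = df[MARKER_COLUMNS].copy()
    return AncestryMatrix(ids=np.array(ids), markers=markers, nam=nam, eur=eur, afr=afr, haplotypes=hap)


# ---------------------------------------------------------------------------
# phenotypes, summary stats, config

def write_phenotypes(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"iid": str})


def write_summary_stats(path: str | Path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant": str, "chrom": str})


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def freeze_config(config: dict, out_dir: str | Path, name: str = "run_config.yaml") -> Path:
    """Write a frozen copy of the effective configuration next to outputs."""
    out = Path(out_dir) / name
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out


def write_truth_yaml(path: str | Path, truth: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(path: str | Path, dosages: DosageMatrix) -> None:
    """Minimal VCF 4.2 with GT hard calls (dosages rounded to 0/1/2).

    The coded allele is written as ALT so that the ALT dosage equals the
    coded-allele dosage on re-import.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, dosages.ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(dosages.n_markers):
            m = dosages.markers.iloc[j]
            calls = []
            for d in dosages.dosage[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[int(round(d))])
            ref = m.get("other", "G")
            alt = m.get("coded", "A")
            fh.write(
                f"{m['chrom']}\t{m['pos']}\t{m['marker']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> DosageMatrix:
    """Read a VCF into a DosageMatrix (DS when present, else GT of ALT).

    Multi-allelic records are dropped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("dropping multi-allelic record %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except Exception:  # field absent from header
            ds = None
        if ds is not None:
            col = np.asarray(ds).reshape(len(ids), -1)[:, 0].astype(float)
        else:
            gts = np.asarray(rec.genotypes)[:, :2]
            col = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        rows.append(
            {"marker": rec.ID or f"{rec.CHROM}:{rec.POS}", "chrom": rec.CHROM, "pos": rec.POS,
             "coded": rec.ALT[0], "other": rec.REF}
        )
        dosage_cols.append(col)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return DosageMatrix(ids=ids, markers=pd.DataFrame(rows), dosage=np.column_stack(dosage_cols))


# ---------------------------------------------------------------------------
# cohort bundles

def write_cohort_bundle(
    out_dir: str | Path,
    ancestry: AncestryMatrix,
    genotypes: DosageMatrix,
    phenotypes: pd.DataFrame,
    truth: dict | None = None,
) -> dict:
    """Write a full cohort (ancestry, genotypes incl. VCF, phenotypes, truth).

    Returns the bundle config (paths) for :func:`read_cohort_bundle`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_ancestry_tsv(out_dir / "ancestry", ancestry)
    if ancestry.haplotypes is not None:
        write_rfmix_calls(out_dir / "ancestry.calls.tsv", ancestry)
    write_dosage_tsv(out_dir / "genotypes", genotypes)
    write_vcf(out_dir / "genotypes.vcf", genotypes)
    write_phenotypes(out_dir / "phenotypes.tsv", phenotypes)
    truth = truth if truth is not None else phenotypes.attrs.get("truth")
    if truth:
        write_truth_yaml(out_dir / "truth.yaml", truth)
    config = {
        "ancestry_prefix": str(out_dir / "ancestry"),
        "dosage_prefix": str(out_dir / "genotypes"),
        "phenotype_path": str(out_dir / "phenotypes.tsv"),
    }
    freeze_config(config, out_dir, "bundle.yaml")
    return config


def read_cohort_bundle(config: dict | str | Path) -> tuple[AncestryMatrix, DosageMatrix, pd.DataFrame]:
    """Load and align a cohort bundle on individual id.

    Inner-joins the three sources on id, logs per-source dropped-id
    counts, and orders individuals deterministically (sorted ids).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    ancestry = read_ancestry_tsv(config["ancestry_prefix"])
    genotypes = read_dosage_tsv(config["dosage_prefix"])
    phenotypes = read_phenotypes(config["phenotype_path"])

    sets = [set(ancestry.ids), set(genotypes.ids), set(map(str, phenotypes["iid"]))]
    common = sorted(sets[0] & sets[1] & sets[2])
    if not common:
        raise ValueError("no individual ids shared across ancestry, genotype and phenotype files")
    for name, s in zip(("ancestry", "genotypes", "phenotypes"), sets):
        dropped = len(s) - len(common)
        if dropped:
            logger.info("read_cohort_bundle: %d ids dropped from %s", dropped, name)

    a_idx = pd.Series(np.arange(len(ancestry.ids)), index=ancestry.ids.astype(str))[common].to_numpy()
    g_idx = pd.Series(np.arange(len(genotypes.ids)), index=genotypes.ids.astype(str))[common].to_numpy()
    ancestry = AncestryMatrix(
        ids=np.array(common), markers=ancestry.markers, nam=ancestry.nam[a_idx],
        eur=None if ancestry.eur is None else ancestry.eur[a_idx],
        afr=None if ancestry.afr is None else ancestry.afr[a_idx],
        haplotypes=None if ancestry.haplotypes is None else ancestry.haplotypes[a_idx],
    )
    genotypes = DosageMatrix(ids=np.array(common), markers=genotypes.markers, dosage=genotypes.dosage[g_idx])
    phenotypes = (
        phenotypes.assign(iid=phenotypes["iid"].astype(str))
        .set_index("iid").loc[common].reset_index()
    )
    return ancestry, genotypes, phenotypes
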