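"""Standard-format I/O: VCF and PLINK text genotypes, clinical CSV, YAML
configuration, TSV artifacts.

Genotype readers return minor-allele counts.  The minor allele is
determined per cohort from observed frequencies; an exact 0.5 tie is broken
toward the ALT allele (VCF) or the lexicographically greater allele (PLINK
text, which carries no REF/ALT orientation).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pgxsig.datatypes import ADDITIVE, DataError, GenotypeMatrix, StructuralError

VCF_HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write one biallelic record per SNP with a GT field per subject.

    The coded (minor) allele is written as ALT, so genotype 2 becomes 1/1.
    """
    lines = [VCF_HEADER]
    samples = "\t".join(str(s) for s in matrix.subject_ids)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp_id in enumerate(matrix.snp_ids):
        rec = matrix.snps.iloc[j]
        calls = [
            gt_map.get(g, "./.") if not np.isnan(g) else "./."
            for g in matrix.data[:, j]
        ]
        lines.append(
            "\t".join(
                ["1", str(1000 + j), str(snp_id), str(rec["ref"]), str(rec["alt"]),
                 ".", "PASS", ".", "GT"] + calls
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF of biallelic SNPs into minor-allele counts."""
    header_cols = None
    snp_rows, data_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header_cols = line.lstrip("#").split("\t")
                continue
            if header_cols is None:
                raise StructuralError(f"line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != len(header_cols):
                raise StructuralError(
                    f"line {lineno}: {len(fields)} fields, expected {len(header_cols)}"
                )
            chrom, pos, snp_id, ref, alt = fields[:5]
            if "," in alt:
                raise DataError(f"line {lineno}: multi-allelic site {snp_id} rejected")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise StructuralError(f"line {lineno}: no GT field")
            gt_idx = fmt.index("GT")
            alt_counts = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    alt_counts.append(np.nan)
                    continue
                try:
                    alleles = [int(a) for a in gt.split("/")]
                except ValueError as exc:
                    raise DataError(f"line {lineno}: bad GT {gt!r}") from exc
                if any(a not in (0, 1) for a in alleles):
                    raise DataError(f"line {lineno}: non-biallelic GT {gt!r}")
                alt_counts.append(float(sum(alleles)))
            snp_rows.append({"snp_id": snp_id, "ref": ref, "alt": alt})
            data_rows.append(alt_counts)
    if not snp_rows:
        raise StructuralError("VCF contains no variant records")
    subject_ids = header_cols[9:]
    data = np.array(data_rows, dtype=float).T  # subjects x snps
    # orient to minor-allele counts; exact 0.5 ties keep ALT as minor
    for j in range(data.shape[1]):
        freq = np.nanmean(data[:, j]) / 2.0
        if freq > 0.5:
            data[:, j] = 2.0 - data[:, j]
            snp_rows[j]["ref"], snp_rows[j]["alt"] = (
                snp_rows[j]["alt"],
                snp_rows[j]["ref"],
            )
    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    snps["coding"] = ADDITIVE
    return GenotypeMatrix(subject_ids, snps, data)


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    map_lines = []
    for j, snp_id in enumerate(matrix.snp_ids):
        map_lines.append(f"1\t{snp_id}\t0\t{1000 + j}")
    prefix.with_suffix(".map").write_text("\n".join(map_lines) + "\n")

    ped_lines = []
    for i, sid in enumerate(matrix.subject_ids):
        cells = [str(sid), str(sid), "0", "0", "0", "-9"]
        for j in range(matrix.n_snps):
            rec = matrix.snps.iloc[j]
            major, minor = str(rec["ref"]), str(rec["alt"])
            g = matrix.data[i, j]
            if np.isnan(g):
                cells += ["0", "0"]
            elif g == 0:
                cells += [major, major]
            elif g == 1:
                cells += [major, minor]
            else:
                cells += [minor, minor]
        ped_lines.append("\t".join(cells))
    prefix.with_suffix(".ped").write_text("\n".join(ped_lines) + "\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text genotypes into minor-allele counts.

    The minor allele per SNP is the less frequent letter; exact ties break
    toward the lexicographically greater letter.
    """
    prefix = Path(prefix)
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    snp_ids = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise StructuralError(f"{map_path}:{lineno}: expected 4 columns")
        snp_ids.append(fields[1])
    if not snp_ids:
        raise StructuralError("empty .map file")

    subject_ids, allele_rows = [], []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * len(snp_ids):
            raise StructuralError(
                f"{ped_path}:{lineno}: {len(fields)} fields, "
                f"expected {6 + 2 * len(snp_ids)}"
            )
        subject_ids.append(fields[1])
        allele_rows.append(fields[6:])

    n, p = len(subject_ids), len(snp_ids)
    data = np.full((n, p), np.nan)
    snp_meta = []
    for j in range(p):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        letters: dict[str, int] = {}
        for a in a1 + a2:
            if a != "0":
                letters[a] = letters.get(a, 0) + 1
        if len(letters) > 2:
            raise DataError(f"SNP {snp_ids[j]}: more than two alleles")
        if not letters:
            minor, major = "N", "N"
        elif len(letters) == 1:
            major = next(iter(letters))
            minor = "N"
        else:
            (x, cx), (y, cy) = sorted(letters.items())
            if cx == cy:
                major, minor = x, y  # tie: greater letter is minor
            elif cx < cy:
                major, minor = y, x
            else:
                major, minor = x, y
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            data[i, j] = float((a1[i] == minor) + (a2[i] == minor))
        snp_meta.append({"snp_id": snp_ids[j], "ref": major, "alt": minor})
    snps = pd.DataFrame(snp_meta).set_index("snp_id")
    snps["coding"] = ADDITIVE
    return GenotypeMatrix(subject_ids, snps, data)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: ``vcf`` or ``plink_text`` (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "plink_text"
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink(path.with_suffix(""))
    raise DataError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# config / artifacts


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError("config must be a YAML mapping")
    return cfg


def dump_yaml_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_fingerprint(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path: str | Path, fingerprint: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if fingerprint is not None:
            fh.write(f"# config_fingerprint: {fingerprint}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
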