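"""On-disk formats and their coordinate conventions.

SEG is the IGV dialect: 1-based inclusive on disk, converted to 0-based
half-open in memory. BEDPE stays 0-based half-open (the breakend is the
interval start). VCF keeps its native 1-based positions. Clinical TSV
uses an en-dash or empty field for missing values. All conversions are
centralized here.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .model import BreakpointJoin, ClinicalRecord, CNSegment, InputError, VariantCall

__all__ = [
    "read_seg",
    "write_seg",
    "read_bedpe",
    "write_bedpe",
    "VcfDialect",
    "read_vcf",
    "write_vcf",
    "read_clinical",
    "write_clinical",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "file_sha256",
]

_MISSING = {"", "-", "–", "NA", "."}

SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def _check_chrom_style(chroms: Sequence[str], path: Union[str, Path]) -> None:
    has_prefix = {c.startswith("chr") for c in chroms}
    if len(has_prefix) > 1:
        raise InputError(f"{path}: mixed chromosome naming (with and without 'chr')")


def normalize_chrom(chrom: str, chr_prefix: Optional[bool]) -> str:
    if chr_prefix is None:
        return chrom
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{bare}" if chr_prefix else bare


def read_seg(path: Union[str, Path], chr_prefix: Optional[bool] = True) -> List[CNSegment]:
    """Read an IGV-dialect SEG file into 0-based half-open segments."""
    path = Path(path)
    segments: List[CNSegment] = []
    chroms: List[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and not _looks_numeric(line.split("\t"), (2, 3)):
                continue  # header
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise InputError(f"{path}:{lineno}: expected 5 or 6 columns, got {len(fields)}")
            try:
                sample = fields[0]
                chrom = normalize_chrom(fields[1], chr_prefix)
                start = int(fields[2]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[3])
                num_mark = int(fields[4]) if len(fields) == 6 and fields[4] not in _MISSING else None
                seg_mean = float(fields[-1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            chroms.append(fields[1])
            segments.append(
                CNSegment(
                    sample=sample,
                    chrom=chrom,
                    start=start,
                    end=end,
                    seg_mean=seg_mean,
                    num_mark=num_mark,
                )
            )
    _check_chrom_style(chroms, path)
    return segments


def _looks_numeric(fields: Sequence[str], idx: Sequence[int]) -> bool:
    try:
        for i in idx:
            int(fields[i])
        return True
    except (ValueError, IndexError):
        return False


def write_seg(segments: Sequence[CNSegment], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEG_HEADER) + "\n")
        for s in segments:
            num_mark = "" if s.num_mark is None else str(s.num_mark)
            fh.write(
                f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{num_mark}\t"
                f"{s.seg_mean:.6g}\n"
            )


def read_bedpe(path: Union[str, Path], chr_prefix: Optional[bool] = True) -> List[BreakpointJoin]:
    """Read standard 10-column BEDPE; the breakend is each interval's start."""
    path = Path(path)
    joins: List[BreakpointJoin] = []
    chroms: List[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise InputError(
                    f"{path}:{lineno}: BEDPE needs 10 columns incl. strands, got {len(fields)}"
                )
            try:
                joins.append(
                    BreakpointJoin(
                        chrom_a=normalize_chrom(fields[0], chr_prefix),
                        pos_a=int(fields[1]),
                        strand_a=fields[8],
                        chrom_b=normalize_chrom(fields[3], chr_prefix),
                        pos_b=int(fields[4]),
                        strand_b=fields[9],
                        name=fields[6],
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            chroms.extend([fields[0], fields[3]])
    _check_chrom_style(chroms, path)
    return joins


def write_bedpe(joins: Sequence[BreakpointJoin], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for j in joins:
            fh.write(
                f"{j.chrom_a}\t{j.pos_a}\t{j.pos_a + 1}\t"
                f"{j.chrom_b}\t{j.pos_b}\t{j.pos_b + 1}\t"
                f"{j.name}\t.\t{j.strand_a}\t{j.strand_b}\n"
            )


@dataclass(frozen=True)
class VcfDialect:
    """Where allele depth lives: a per-sample AD-style FORMAT field
    (default) or a pair of INFO counts."""

    source: str = "format_ad"  # "format_ad" | "info"
    ad_field: str = "AD"
    info_alt_field: str = "ALTREADS"
    info_depth_field: str = "DP"
    compartment_info_field: str = "CMP"


def read_vcf(
    path: Union[str, Path],
    dialect: VcfDialect = VcfDialect(),
    default_compartment: str = "somatic",
) -> List[VariantCall]:
    """Read VCF v4.2 into one VariantCall per ALT allele."""
    from cyvcf2 import VCF  # heavy import kept local

    calls: List[VariantCall] = []
    vcf = VCF(str(path))
    for rec in vcf:
        compartment = rec.INFO.get(dialect.compartment_info_field) or default_compartment
        db_match = bool(rec.INFO.get("DB", False))
        if dialect.source == "format_ad":
            ad = rec.format(dialect.ad_field)
            if ad is None:
                raise InputError(
                    f"{path}: FORMAT field {dialect.ad_field!r} absent at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            ad = ad[0]  # first (only) sample
            depth = int(sum(int(x) for x in ad if x >= 0))
            alt_counts = [int(x) for x in ad[1:]]
        else:
            alt_val = rec.INFO.get(dialect.info_alt_field)
            depth_val = rec.INFO.get(dialect.info_depth_field)
            if alt_val is None or depth_val is None:
                raise InputError(
                    f"{path}: INFO fields {dialect.info_alt_field!r}/"
                    f"{dialect.info_depth_field!r} absent at {rec.CHROM}:{rec.POS}"
                )
            alt_counts = [int(x) for x in (alt_val if isinstance(alt_val, tuple) else (alt_val,))]
            depth = int(depth_val)
        qual = None if rec.QUAL is None else float(rec.QUAL)
        for alt, alt_reads in zip(rec.ALT, alt_counts):
            calls.append(
                VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qual=qual,
                    alt_reads=alt_reads,
                    total_depth=depth,
                    compartment=compartment,
                    database_match=db_match,
                )
            )
    return calls


def write_vcf(
    variants: Sequence[VariantCall],
    path: Union[str, Path],
    sample: str = "SAMPLE",
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write VCF v4.2 with AD/DP FORMAT fields and a CMP INFO tag."""
    path = Path(path)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=CMP,Number=1,Type=String,Description="Compartment">\n')
        fh.write('##INFO=<ID=DB,Number=0,Type=Flag,Description="Curated database match">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in ordered:
            qual = "." if v.qual is None else f"{v.qual:.6g}"
            info = f"CMP={v.compartment}"
            if v.database_match:
                info += ";DB"
            ref_reads = v.total_depth - v.alt_reads
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\tPASS\t{info}\t"
                f"AD:DP\t{ref_reads},{v.alt_reads}:{v.total_depth}\n"
            )


_CLINICAL_COLUMNS = [
    "id",
    "age",
    "histology",
    "dose_gy",
    "field",
    "latency_y",
    "status",
    "survival_months",
]

_FLOAT_RE = re.compile(r"-?\d+(?:\.\d+)?")


def _parse_missing_float(text: str) -> Optional[float]:
    if text.strip() in _MISSING:
        return None
    return float(text)


def read_clinical(path: Union[str, Path]) -> List[ClinicalRecord]:
    """Read the clinical TSV; en-dash, hyphen, or empty marks missing.

    Free-text dose entries (multi-course doses, unknown components) keep
    their raw string; ``dose_gy`` is the first parseable number, if any.
    """
    path = Path(path)
    records: List[ClinicalRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CLINICAL_COLUMNS:
            raise InputError(f"{path}: expected columns {_CLINICAL_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(_CLINICAL_COLUMNS):
                raise InputError(f"{path}:{lineno}: expected {len(_CLINICAL_COLUMNS)} columns")
            row = dict(zip(_CLINICAL_COLUMNS, fields))
            dose_raw = None if row["dose_gy"].strip() in _MISSING else row["dose_gy"].strip()
            dose = None
            if dose_raw is not None:
                m = _FLOAT_RE.search(dose_raw)
                dose = float(m.group()) if m else None
            status_txt = row["status"].strip()
            if status_txt in _MISSING:
                status = None
            elif status_txt in ("D", "deceased"):
                status = "deceased"
            else:
                raise InputError(f"{path}:{lineno}: unknown status {status_txt!r}")
            try:
                records.append(
                    ClinicalRecord(
                        case_id=row["id"],
                        age=_parse_missing_float(row["age"]),
                        histology=None if row["histology"] in _MISSING else row["histology"],
                        dose_gy=dose,
                        dose_raw=dose_raw,
                        field_type=None if row["field"] in _MISSING else row["field"],
                        latency_y=_parse_missing_float(row["latency_y"]),
                        status=status,
                        survival_months=_parse_missing_float(row["survival_months"]),
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: Union[str, Path]) -> None:
    def fmt(v) -> str:
        return "–" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))

    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            dose = r.dose_raw if r.dose_raw is not None else r.dose_gy
            status = "D" if r.status == "deceased" else None
            fh.write(
                "\t".join(
                    [
                        r.case_id,
                        fmt(r.age),
                        fmt(r.histology),
                        fmt(dose),
                        fmt(r.field_type),
                        fmt(r.latency_y),
                        fmt(status),
                        fmt(r.survival_months),
                    ]
                )
                + "\n"
            )


def write_ground_truth(truth, path: Union[str, Path]) -> None:
    payload = {
        "samples": {name: asdict(st) for name, st in truth.samples.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: Union[str, Path],
    config: dict,
    seed: int,
    inputs: Dict[str, Union[str, Path]],
    outputs: Dict[str, Union[str, Path]],
) -> None:
    """Reproducibility manifest: config snapshot, seed, and file digests.

    Deliberately contains no wall-clock timestamp so that identical runs
    produce byte-identical manifests.
    """
    manifest = {
        "config": config,
        "seed": seed,
        "inputs": {k: file_sha256(v) for k, v in sorted(inputs.items())},
        "outputs": {k: file_sha256(v) for k, v in sorted(outputs.items())},
        "version": _package_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("rigstruct")
    except Exception:
        return "unknown"
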