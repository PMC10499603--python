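"""File formats, configuration and report writing.

FASTA handles sequences (Biopython dialect, wrapped or unwrapped), CSV
handles all tables, and locus definitions live in a small YAML config.
Reports embed run metadata (package version, seed, config hash) as ``#``
comment lines above the CSV header; all coordinates written are 0-based,
half-open.  Report writing is deterministic: re-running on the same inputs
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .junctions import ReferenceLocus, SampleSummary

logger = logging.getLogger(__name__)

IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records from a FASTA file.

    Sequences are upper-cased.  Duplicate ids, empty files and non-IUPAC
    nucleotide characters are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_NT:
                raise ValueError(
                    f"non-IUPAC character {ch!r} at position {pos} of record "
                    f"{rec.id!r} in {path}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[tuple[str, str]], path: Union[str, Path], width: int = 70
) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_locus_config(path: Union[str, Path]) -> ReferenceLocus:
    """Load a locus definition from YAML.

    Keys: ``name``, ``cut_position``, ``fwd_primer``, ``rev_primer``,
    ``enzyme_recognition``, ``recognition_site_span`` ([start, end),
    0-based), and either ``amplicon`` (inline) or ``amplicon_fasta``
    (path, resolved relative to the config file; first record used).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "amplicon" in cfg:
        amplicon = cfg["amplicon"]
    elif "amplicon_fasta" in cfg:
        fasta = Path(cfg["amplicon_fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        amplicon = read_fasta(fasta)[0][1]
    else:
        raise ValueError("locus config needs 'amplicon' or 'amplicon_fasta'")
    span = cfg.get("recognition_site_span")
    return ReferenceLocus(
        name=cfg["name"],
        amplicon=amplicon,
        cut_position=int(cfg["cut_position"]),
        fwd_primer=cfg["fwd_primer"],
        rev_primer=cfg["rev_primer"],
        enzyme_recognition=cfg.get("enzyme_recognition", "GGTGA"),
        recognition_site_span=tuple(span) if span is not None else None,
    )


def write_locus_config(
    locus: ReferenceLocus, path: Union[str, Path], inline_amplicon: bool = True
) -> None:
    """Write a locus definition as YAML (amplicon inline by default)."""
    cfg = {
        "name": locus.name,
        "amplicon": locus.amplicon,
        "cut_position": locus.cut_position,
        "fwd_primer": locus.fwd_primer,
        "rev_primer": locus.rev_primer,
        "enzyme_recognition": locus.enzyme_recognition,
        "recognition_site_span": list(locus.recognition_site_span)
        if locus.recognition_site_span
        else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv_with_header(
    df: pd.DataFrame, path: Path, meta: dict, overwrite: bool
) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    lines = [f"# mitoej {__version__}", "# coordinates: 0-based, half-open"]
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def write_report(
    out_dir: Union[str, Path],
    calls: pd.DataFrame,
    summary: Optional[SampleSummary] = None,
    config: Optional[dict] = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write per-read calls (and optionally a sample summary) as CSV.

    Run metadata -- package version, coordinate convention, the caller
    configuration and its hash -- is embedded as ``#`` comment lines.
    Existing files are refused unless ``overwrite`` is set.  Output is
    deterministic (no timestamps), so identical inputs give byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or {}
    meta = dict(config)
    meta["config_hash"] = config_hash(config)
    written: dict[str, Path] = {}

    calls_path = out_dir / "junction_calls.csv"
    _write_csv_with_header(calls, calls_path, meta, overwrite)
    written["calls"] = calls_path

    if summary is not None:
        rows = [
            {"metric": "n_reads_in", "value": summary.n_reads_in},
            {"metric": "n_events", "value": summary.n_events},
            {"metric": "n_unmodified", "value": summary.n_unmodified},
            {"metric": "n_unclassified", "value": summary.n_unclassified},
            {"metric": "fraction_mh", "value": summary.fraction_mh},
            {"metric": "median_deletion", "value": summary.median_deletion},
        ]
        for verdict, count in sorted(summary.n_excluded_by_filter.items()):
            rows.append({"metric": f"excluded[{verdict}]", "value": count})
        for bin_label, count in summary.deletion_size_histogram.items():
            rows.append({"metric": f"deletions[{bin_label}]", "value": count})
        summary_path = out_dir / "sample_summary.csv"
        _write_csv_with_header(pd.DataFrame(rows), summary_path, meta, overwrite)
        written["summary"] = summary_path
    return written


def read_wells_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Screen well table (plate,row,col,replicate,gene,sirna,role,value)."""
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values=[""], dtype={"gene": str, "sirna": str})
    required = {"plate", "row", "col", "replicate", "gene", "sirna", "role",
                "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well table {path} lacks columns {sorted(missing)}")
    df["gene"] = df["gene"].fillna("")
    df["sirna"] = df["sirna"].fillna("")
    return df


def read_qpcr_csv(path: Union[str, Path]) -> pd.DataFrame:
    """qPCR Ct table (sample,condition,ct_target,ct_norm)."""
    df = pd.read_csv(path, comment="#")
    required = {"sample", "condition", "ct_target", "ct_norm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table {path} lacks columns {sorted(missing)}")
    return df


def read_bli_csv(path: Union[str, Path]) -> pd.DataFrame:
    """BLI table (ligand,concentration_nM,response)."""
    df = pd.read_csv(path, comment="#")
    required = {"ligand", "concentration_nM", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"BLI table {path} lacks columns {sorted(missing)}")
    return df
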