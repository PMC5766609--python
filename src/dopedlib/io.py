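"""Readers, writers and packaged fixtures.

Formats: FASTA for plain DNA/peptide sequences (Biopython), CSV for
activity tables (censored cells encoded ``">bound"``; peptides with
D-residues or side-chain modifiers use the extended sequence encoding and
never FASTA), TSV for selection-pool dumps, JSON for run manifests.
Peptide coordinates are 1-based; DNA coordinates 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pharm import EC50, ActivityRecord, PeptideSeq

logger = logging.getLogger("dopedlib")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_activity_csv",
    "write_activity_csv",
    "records_from_frame",
    "load_phage_peptides",
    "load_engineered_peptides",
    "fixture_sha256",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_manifest",
    "load_config",
]


class ParseError(ValueError):
    """Malformed record; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "peptide") -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; lowercase is normalized to uppercase
    with a warning (``alphabet`` is 'peptide' or 'dna')."""
    from Bio import SeqIO

    allowed = set("ACGT") if alphabet == "dna" else set("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning("sequence %s contains lowercase; normalizing",
                           rec.id)
            seq = seq.upper()
        bad = set(seq) - allowed
        if bad:
            raise ParseError(
                f"record {rec.id}: invalid {alphabet} characters {bad}")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(s), id=str(i), description="")
                 for i, s in records], str(path), "fasta")


# ---------------------------------------------------------------------------
# activity tables

def records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(ActivityRecord(
                peptide_id=str(row.id),
                sequence=PeptideSeq.parse(str(row.sequence)),
                gcgr=EC50.parse(row.ec50_gcgr, getattr(row, "sd_gcgr", None)),
                glp1r=EC50.parse(row.ec50_glp1r,
                                 getattr(row, "sd_glp1r", None)),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"line {line}: {exc}") from exc
    return records


def read_activity_csv(path) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Read an activity CSV (columns id, sequence, ec50_gcgr, sd_gcgr,
    ec50_glp1r, sd_glp1r, ...); returns parsed records and the raw frame."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"id", "sequence", "ec50_gcgr", "ec50_glp1r"} - set(df.columns)
    if missing:
        raise ParseError(f"activity table missing columns {sorted(missing)}")
    return records_from_frame(df), df


def write_activity_csv(records: Sequence[ActivityRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.peptide_id,
            "sequence": str(r.sequence),
            "ec50_gcgr": (f">{r.gcgr.censor_bound:g}" if r.gcgr.is_censored
                          else f"{r.gcgr.mean:g}"),
            "sd_gcgr": "" if r.gcgr.sd is None else f"{r.gcgr.sd:g}",
            "ec50_glp1r": (f">{r.glp1r.censor_bound:g}"
                           if r.glp1r.is_censored else f"{r.glp1r.mean:g}"),
            "sd_glp1r": "" if r.glp1r.sd is None else f"{r.glp1r.sd:g}",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged fixtures

def _fixture_path(name: str):
    return resources.files("dopedlib.data") / name


def _load_fixture(name: str) -> tuple[list[ActivityRecord], pd.DataFrame]:
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    return records_from_frame(df), df


def load_phage_peptides() -> tuple[list[ActivityRecord], pd.DataFrame]:
    """The 35 phage-derived glucagon-backbone peptides with their GCGR and
    GLP1R EC50s (nM) and the ratio column as originally printed."""
    return _load_fixture("phage_peptides.csv")


def load_engineered_peptides() -> tuple[list[ActivityRecord], pd.DataFrame]:
    """The two engineered analogues (D-Ser2 + K10(γEγEC16)) alongside the
    parent peptides they derive from, sequences as printed in the source
    comparison table (including its R18A reading of parent 16)."""
    return _load_fixture("engineered_peptides.csv")


def fixture_sha256(name: str) -> str:
    with resources.as_file(_fixture_path(name)) as p:
        return hashlib.sha256(Path(p).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pools

def write_pool_tsv(pool, path, parent: str | None = None) -> None:
    """Serialize a selection pool: peptide, count, latent potencies."""
    from .screen import GLUCAGON

    parent = parent or GLUCAGON
    rows = []
    for key, count in sorted(pool.counts.items(), key=lambda kv: str(kv[0])):
        v = pool.variants[key]
        row = {
            "peptide": v.peptide(parent),
            "count": count,
            "mutations": ";".join(f"{p}{aa}" for p, aa in key) or "wt",
        }
        if v.log_ec50 is not None:
            row["log10_ec50_gcgr"], row["log10_ec50_glp1r"] = v.log_ec50
            row["binder_only"] = int(v.binder_only)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pool_tsv(path, parent: str | None = None):
    from .screen import GLUCAGON, call_mutations
    from .simulate import PoolState, Variant

    parent = parent or GLUCAGON
    df = pd.read_csv(path, sep="\t")
    variants, counts = {}, {}
    for _, row in df.iterrows():
        calls = call_mutations(str(row["peptide"]), parent)
        key = tuple(sorted((c.position, c.observed) for c in calls))
        log_ec50 = None
        binder_only = False
        if "log10_ec50_gcgr" in df.columns:
            log_ec50 = (float(row["log10_ec50_gcgr"]),
                        float(row["log10_ec50_glp1r"]))
            binder_only = bool(int(row.get("binder_only", 0)))
        variants[key] = Variant(mutations=key, log_ec50=log_ec50,
                                binder_only=binder_only)
        counts[key] = int(row["count"])
    return PoolState(round_index=0, variants=variants, counts=counts)


# ---------------------------------------------------------------------------
# manifests and config

def write_manifest(path, config: dict, seeds) -> None:
    from . import __version__

    payload = {
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def load_config(path) -> dict:
    """Load a YAML run configuration (flat, human-editable)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} is not a mapping")
    return cfg
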