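"""Readers, writers and reports: FASTA, genotype tables, JSON manifests."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .caps import BandPattern, CAPSMarker, GelModel, patterns_distinguishable
from .genotypes import PRS_LOCI, LocusCall, SSIRecord


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def read_fasta(path) -> list[FastaRecord]:
    """Read FASTA records; IDs are the header up to the first whitespace.

    Sequences are uppercased and U is normalized to T; alignment gaps are
    preserved.  An empty file yields an empty list with a warning.
    """
    records = [
        FastaRecord(rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs or FastaRecord/GeneratedClone objects."""
    seqs = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = rec.id, rec.sequence
        seqs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqs, str(path), "fasta")


@dataclass(frozen=True)
class GenotypeTableSchema:
    """Column layout of a delimited SSI genotype table (tab-separated)."""

    id_column: str = "id"
    locus_columns: tuple[str, ...] = PRS_LOCI
    band_columns: tuple[str, str] = ("ITS_MboII", "ITS_FokI")


DEFAULT_SCHEMA = GenotypeTableSchema()


def _parse_band_list(token) -> tuple[int, ...]:
    token = "" if token is None else str(token).strip()
    if not token or token.lower() == "nan":
        return ()
    return tuple(int(x) for x in token.replace(" ", "").split("+") if x)


def phenotype_from_bands(mboii_bands, foki_bands, marker: CAPSMarker) -> str | None:
    """Map an (MboII, FokI) informative band pair to its ITS phenotype class.

    Bands are compared with the marker's gel co-migration tolerance; the
    match must be unique, otherwise the phenotype is undetermined (None).
    """
    from .caps import its_phenotype

    obs = (_parse_band_list(mboii_bands), _parse_band_list(foki_bands))
    if not obs[0] and not obs[1]:
        return None
    matches = []
    for r in range(1, 4):
        import itertools
        for combo in itertools.combinations(sorted(marker.alleles), r):
            label, patterns = its_phenotype(combo, marker)
            expected = tuple(p.informative for p in patterns.values())
            if all(
                len(o) == len(e) and all(marker.gel.comigrate(x, y) for x, y in zip(o, e))
                for o, e in zip(obs, expected)
            ):
                matches.append(label)
    return matches[0] if len(matches) == 1 else None


def read_genotype_table(path, schema: GenotypeTableSchema = DEFAULT_SCHEMA,
                        marker: CAPSMarker | None = None) -> list[SSIRecord]:
    """Load a tab-separated SSI genotype table into typed records.

    Blank or unknown tokens become undetermined calls (logged); the ITS
    phenotype class is recovered from the band columns via the marker
    fixture's expected patterns.
    """
    from . import fixtures

    marker = marker or fixtures.its_marker()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (schema.id_column, *schema.locus_columns) if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table is missing mandatory column(s): {missing}")
    records = []
    n_undetermined = 0
    for _, row in df.iterrows():
        calls = {}
        for locus in schema.locus_columns:
            call = LocusCall.parse(locus, row.get(locus))
            if call is None:
                n_undetermined += 1
            calls[locus] = call
        phenotype = None
        if all(c in df.columns for c in schema.band_columns):
            phenotype = phenotype_from_bands(
                row.get(schema.band_columns[0]), row.get(schema.band_columns[1]), marker
            )
        records.append(SSIRecord(str(row[schema.id_column]), calls, phenotype))
    if n_undetermined:
        warnings.warn(f"{n_undetermined} undetermined locus call(s) in {path}")
    return records


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _to_jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(results: dict, path, fmt: str = "json", seed=None, config=None) -> None:
    """Write an analysis report with a reproducibility manifest.

    JSON keeps full precision; the text format rounds display values to two
    decimals.  The manifest records package version, seed and a config hash.
    """
    payload = _to_jsonable(results)
    manifest = {
        "package": "itsloci",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(_to_jsonable(config), sort_keys=True).encode()
        ).hexdigest() if config is not None else None,
    }
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps({"manifest": manifest, "results": payload}, indent=2) + "\n")
    elif fmt == "tsv":
        flat = _flatten(payload)
        pd.DataFrame(sorted(flat.items()), columns=["key", "value"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "text":
        lines = [f"# itsloci {__version__}" + (f" (seed={seed})" if seed is not None else "")]
        for key, value in _flatten(payload).items():
            if isinstance(value, float):
                value = f"{value:.2f}"
            lines.append(f"{key}: {value}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _flatten(d, prefix="") -> dict:
    if not isinstance(d, dict):
        return {prefix or "value": d}
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out
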