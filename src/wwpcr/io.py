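"""Readers/writers for FASTA, primer tables, run configuration and reports.

The bundled primer table ships the validated three-WWP set and the two
published GSP nests (for the glutamate-decarboxylase and hygromycin walks);
`load_published_primers` returns them as records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import PrimerRecord, WWPArchitecture
from .errors import DegenerateBaseError, FormatError
from .sim import CyclingProfile, WalkResult, default_profiles
from .thermo import ThermoModel, validate_dna


def read_fasta(path, allow_degenerate: bool = False) -> List[SeqRecord]:
    """Read a (multi-record) FASTA file; sequences are uppercased.

    By default any non-ACGT character is rejected with a degenerate-base
    error, because the thermodynamic model has no semantics for ambiguity
    codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not allow_degenerate:
            validate_dna(seq, what=f"record {rec.id!r}")
        out.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    return out


def write_fasta(records: Sequence, path) -> None:
    """Write records ((id, seq) pairs or SeqRecords) as wrapped FASTA."""
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(SeqRecord(Seq(str(r.seq).upper()), id=r.id,
                                  description=""))
        else:
            rid, seq = r
            recs.append(SeqRecord(Seq(seq.upper()), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_primer_table(path) -> List[PrimerRecord]:
    """Read a TSV primer table (columns: name, sequence, role, tier)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse primer table {path}: {exc}") from exc
    required = {"name", "sequence", "role"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"primer table must have columns {sorted(required)} "
            f"(got {list(df.columns)})"
        )
    names = df["name"].tolist()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate primer names: {sorted(dupes)}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            tier = row.get("tier")
            tier = int(tier) if tier is not None and not pd.isna(tier) else None
            records.append(PrimerRecord(
                name=str(row["name"]),
                sequence=str(row["sequence"]),
                role=str(row["role"]),
                tier=tier,
            ))
        except (DegenerateBaseError, ValueError) as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return records


def load_published_primers() -> List[PrimerRecord]:
    """The bundled published primer set: 3 WWPs and two GSP nests."""
    ref = resources.files("wwpcr").joinpath("data/published_primers.tsv")
    with resources.as_file(ref) as p:
        return read_primer_table(p)


def write_report(result: WalkResult, out_prefix) -> Dict[str, Path]:
    """Write a walk result as JSON ledger, BED6 band track and band TSV."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_prefix.with_suffix(".json"),
        "bed": out_prefix.with_suffix(".bed"),
        "tsv": out_prefix.with_suffix(".tsv"),
    }
    paths["json"].write_text(result.to_json(indent=2) + "\n")
    from .sim import predict_band_pattern

    bands = predict_band_pattern(result)
    with open(paths["bed"], "w") as fh:
        for b in bands:
            fh.write(
                f"{result.genome_id}\t{b.start}\t{b.end}\t{b.primer_pair}"
                f"\t{b.round_created}\t{b.strand}\n"
            )
    with open(paths["tsv"], "w") as fh:
        fh.write("size\tstart\tend\tstrand\tprimer_pair\tround\n")
        for b in bands:
            fh.write(
                f"{b.size}\t{b.start}\t{b.end}\t{b.strand}\t{b.primer_pair}"
                f"\t{b.round_created}\n"
            )
    return paths


@dataclass
class RunConfig:
    """Complete run configuration; defaults equal the published protocol
    (stage cycles 5/1/25; annealing 65/25/65 degC primary, 65/40/65 degC
    secondary and tertiary; 25-nt 12+10+3 primer architecture)."""

    thermo: ThermoModel = field(default_factory=ThermoModel)
    architecture: WWPArchitecture = field(default_factory=WWPArchitecture)
    profiles: List[CyclingProfile] = field(default_factory=default_profiles)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "thermo": asdict(self.thermo),
            "architecture": asdict(self.architecture),
            "profiles": [asdict(p) for p in self.profiles],
            "seed": self.seed,
        }
        for a in d["architecture"], *d["profiles"]:
            for k, v in a.items():
                if isinstance(v, tuple):
                    a[k] = list(v)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _tup(obj, keys):
            return {
                k: tuple(v) if k in keys and isinstance(v, list) else v
                for k, v in obj.items()
            }

        return cls(
            thermo=ThermoModel(**d.get("thermo", {})),
            architecture=WWPArchitecture(
                **_tup(d.get("architecture", {}), {"self_tm_window"})
            ),
            profiles=[
                CyclingProfile(**_tup(p, {"stage1", "stage2", "stage3"}))
                for p in d.get("profiles", [])
            ] or default_profiles(),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
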