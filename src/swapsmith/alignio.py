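"""Alignment file I/O: PIR (Modeller dialect) and FASTA.

The PIR dialect used by Modeller carries two header lines per entry::

    >P1;code
    structureX:file:begin:chain:end:chain:::-1.00:-1.00
    MSEQ...*

``structureX`` marks the template (coordinates available); ``sequence``
marks the modeling target.  Sequences end with ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["PirEntry", "write_pir", "read_pir", "write_fasta", "read_fasta"]


@dataclass
class PirEntry:
    code: str
    kind: str  # "structureX" | "sequence"
    gapped_seq: str
    source_file: str = ""
    begin: str = ""
    chain: str = ""
    end: str = ""

    def header_line(self) -> str:
        return (
            f"{self.kind}:{self.source_file}:{self.begin}:{self.chain}:"
            f"{self.end}:{self.chain}:::-1.00:-1.00"
        )


def write_pir(entries: list[PirEntry], path: str | Path, width: int = 75) -> Path:
    path = Path(path)
    lines = []
    for e in entries:
        if e.kind not in ("structureX", "sequence"):
            raise ValueError(f"unknown PIR entry kind {e.kind!r}")
        lines.append(f">P1;{e.code}")
        lines.append(e.header_line())
        body = e.gapped_seq + "*"
        for i in range(0, len(body), width):
            lines.append(body[i : i + width])
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pir(path: str | Path) -> list[PirEntry]:
    entries: list[PirEntry] = []
    code = None
    header = None
    seq_parts: list[str] = []

    def flush():
        nonlocal code, header, seq_parts
        if code is None:
            return
        seq = "".join(seq_parts)
        if not seq.endswith("*"):
            raise ValueError(f"PIR entry {code} does not end with '*'")
        fields = (header or "").split(":")
        entries.append(
            PirEntry(
                code=code,
                kind=fields[0] if fields else "",
                gapped_seq=seq[:-1],
                source_file=fields[1] if len(fields) > 1 else "",
                begin=fields[2] if len(fields) > 2 else "",
                chain=fields[3] if len(fields) > 3 else "",
                end=fields[4] if len(fields) > 4 else "",
            )
        )
        code, header, seq_parts = None, None, []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith(">P1;"):
            flush()
            code = line[4:].strip()
            header = None
        elif code is not None and header is None:
            header = line
        elif code is not None:
            seq_parts.append(line)
    flush()
    return entries


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        path,
        "fasta",
    )
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio.SeqIO import parse as seqio_parse

    return [(rec.id, str(rec.seq)) for rec in seqio_parse(Path(path), "fasta")]
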