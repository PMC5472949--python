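"""Minimal GMT (gene matrix transposed) reader/writer.

One gene set per line: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

from pathlib import Path

from .datasets import canonical_gene_id
from .errors import InputError


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{ln}: GMT line needs name, description and >= 1 gene")
        name = fields[0]
        if name in sets:
            raise InputError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = [canonical_gene_id(g) for g in fields[2:] if g.strip()]
    if not sets:
        raise InputError(f"{path}: empty GMT file")
    return sets


def write_gmt(path, sets: dict[str, list[str]], description: str = "") -> None:
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, description or name] + [str(g) for g in genes]))
    Path(path).write_text("\n".join(lines) + "\n")
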