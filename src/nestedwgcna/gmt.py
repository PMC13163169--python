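"""GMT gene-set file reading and writing.

GMT is the tab-delimited gene-set format used throughout enrichment
tooling: one set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
Module outputs (CGMs, cores, FGMs) and TF-target maps both travel as GMT.
"""

from __future__ import annotations

from pathlib import Path

from .matrix import ValidationError

__all__ = ["read_gmt", "write_gmt"]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: genes}``; duplicate names rejected."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{Path(path).name}:{lineno}: GMT line needs name, "
                    "description and at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ValidationError(
                    f"{Path(path).name}:{lineno}: duplicate set name {name!r}"
                )
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(
    sets: dict[str, list[str] | set[str]],
    path: str | Path,
    description: str = "nestedwgcna",
) -> None:
    """Write gene sets as GMT; genes are sorted for reproducible output."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")
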