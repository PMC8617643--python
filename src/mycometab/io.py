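"""Plain-text I/O helpers: GMT set files and annotation tables."""

from __future__ import annotations

import pandas as pd


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """Write named feature sets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    lines = "".join(
        "\t".join([name, descriptions.get(name, "na"), *sets[name]]) + "\n" for name in sets
    )
    if hasattr(path, "write"):
        path.write(lines)
    else:
        with open(path, "w") as fh:
            fh.write(lines)


def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = parts[2:]
            descriptions[parts[0]] = parts[1]
    return sets, descriptions


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out["pathway_ids"] = [";".join(p) for p in out["pathway_ids"]]
    out.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    ann["pathway_ids"] = [
        p.split(";") if isinstance(p, str) and p else [] for p in ann["pathway_ids"]
    ]
    return ann
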