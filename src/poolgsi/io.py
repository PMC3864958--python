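"""Readers and writers for the pipeline's exchange formats.

Native interchange is headered TSV with ``#``-prefixed provenance comment
lines; individual genotypes additionally round-trip through Genepop
(two-digit biallelic coding).  Frequency tables from independent surveys
can be merged on shared loci with explicit allele-orientation handling —
flips are never applied silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allelotyping import ClusterReference
from .gsi import GenotypeMatrix
from .tables import AlleleFrequencyTable

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "read_cluster_reference",
    "write_cluster_reference",
    "read_replicate_thetas",
    "write_replicate_thetas",
    "read_panel_map",
    "write_panel_map",
    "read_genepop",
    "write_genepop",
    "write_distance_matrix",
    "write_phylip_matrix",
    "write_fit_json",
    "merge_frequency_datasets",
    "MergeReport",
]

_FLOAT_FMT = "%.8g"


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}={v}" for k, v in provenance.items()]


def _write_tsv(df: pd.DataFrame, path, provenance=None, index_label=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def write_frequency_table(
    table: AlleleFrequencyTable, path, provenance: dict | None = None
) -> None:
    """Write a frequency TSV (rows=loci, columns=populations) plus a
    ``<path>.sizes`` sidecar with per-population pool sizes."""
    _write_tsv(table.freq, path, provenance, index_label="locus_id")
    sizes = table.n_individuals.rename("n_individuals").to_frame()
    sizes.index.name = "population"
    sizes.to_csv(str(path) + ".sizes", sep="\t")


def read_frequency_table(path, default_n: int = 50) -> AlleleFrequencyTable:
    """Read a frequency TSV; pool sizes come from the ``.sizes`` sidecar
    when present, else ``default_n`` per population."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate locus ids in {path}: {dups[:5]}")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~((arr >= 0) & (arr <= 1)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"frequency out of range in {path} at locus {df.index[i]!r}, "
            f"population {df.columns[j]!r}: {arr[i, j]!r}"
        )
    sizes_path = Path(str(path) + ".sizes")
    if sizes_path.exists():
        sizes = pd.read_csv(sizes_path, sep="\t", index_col=0)["n_individuals"]
        sizes.index = sizes.index.astype(str)
    else:
        sizes = pd.Series(float(default_n), index=df.columns)
    return AlleleFrequencyTable(df, sizes)


def write_cluster_reference(ref: ClusterReference, path, provenance=None) -> None:
    _write_tsv(ref.table, path, provenance, index_label="locus_id")


def read_cluster_reference(path) -> ClusterReference:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return ClusterReference(df)


def write_replicate_thetas(thetas: pd.DataFrame, path, provenance=None) -> None:
    """Replicate theta TSV: population, replicate, then one column per locus."""
    _write_tsv(thetas, path, provenance)


def read_replicate_thetas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["population"] = df["population"].astype(str)
    return df.set_index(["population", "replicate"])


def write_panel_map(panel_map: pd.DataFrame, path, provenance=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        panel_map.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index=False)


def read_panel_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locus_id", "chromosome", "position_cM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel map missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Genepop


def write_genepop(gm: GenotypeMatrix, path, title: str = "poolgsi export") -> None:
    """Two-digit biallelic Genepop: allele 01 = A, 02 = B; dosage 0/1/2
    maps to 0101/0102/0202."""
    code = {0: "0101", 1: "0102", 2: "0202"}
    path = Path(path)
    with path.open("w") as fh:
        fh.write(title + "\n")
        for locus in gm.loci:
            fh.write(locus + "\n")
        pops = list(dict.fromkeys(gm.origin))
        for pop in pops:
            fh.write("POP\n")
            rows = gm.genotypes.loc[gm.origin.to_numpy() == pop]
            for i, (_, row) in enumerate(rows.iterrows(), start=1):
                geno = " ".join(code[int(v)] for v in row)
                fh.write(f"{pop}_{i} ,  {geno}\n")


def read_genepop(path, role: str = "baseline") -> GenotypeMatrix:
    """Read a two-digit biallelic Genepop file; missing genotypes (0000)
    are rejected (the downstream contract is complete data)."""
    lines = [l.rstrip("\n") for l in Path(path).open()]
    if not lines:
        raise ValueError("empty genepop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(l.strip() for l in body[i].split(",") if l.strip())
        i += 1
    if i == len(body):
        raise ValueError("genepop file has no POP record")
    genos: list[list[int]] = []
    labels: list[str] = []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = body[i]
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise ValueError(f"malformed genepop line: {line!r}")
        name, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        row = []
        for locus, tok in zip(loci, tokens):
            if len(tok) != 4 or not tok.isdigit():
                raise ValueError(f"bad genotype token {tok!r} at locus {locus}")
            a1, a2 = int(tok[:2]), int(tok[2:])
            if a1 == 0 or a2 == 0:
                raise ValueError(
                    f"missing genotype {tok!r} at locus {locus} "
                    f"(complete data required)"
                )
            if a1 > 2 or a2 > 2:
                raise ValueError(
                    f"more than two alleles at locus {locus}: token {tok!r}"
                )
            row.append((a1 == 2) + (a2 == 2))
        genos.append(row)
        # population label: use first individual's prefix, else index
        labels.append(name.strip().rsplit("_", 1)[0] or f"pop{pop_idx}")
        i += 1
    g = pd.DataFrame(genos, columns=loci)
    return GenotypeMatrix(g, pd.Series(labels), role)


# ---------------------------------------------------------------------------
# distance matrices, trees, fits


def write_distance_matrix(d: pd.DataFrame, path, provenance=None) -> None:
    _write_tsv(d, path, provenance, index_label="population")


def write_phylip_matrix(d: pd.DataFrame, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{len(d)}\n")
        for name in d.index:
            vals = " ".join(f"{v:.6f}" for v in d.loc[name])
            fh.write(f"{str(name)[:10]:<10} {vals}\n")


def write_fit_json(fit, path, extra: dict | None = None) -> None:
    payload = {
        "a": fit.a,
        "b": fit.b,
        "required_x": {str(k): v for k, v in fit.required_x.items()},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# merging independent frequency datasets


@dataclass
class MergeReport:
    shared_loci: list[str]
    dropped_a: list[str]
    dropped_b: list[str]
    flipped: list[str] = field(default_factory=list)


def merge_frequency_datasets(
    a: AlleleFrequencyTable,
    b: AlleleFrequencyTable,
    allele_key: dict[str, str] | str | None = None,
) -> tuple[AlleleFrequencyTable, MergeReport]:
    """Merge two frequency tables on shared loci (population union).

    ``allele_key`` states, per shared locus, whether ``b`` reports the same
    allele as ``a`` (``"same"``) or the opposite (``"flip"``, stored as
    1-p).  Pass the string ``"same"`` to declare a uniform orientation.
    Without a key the orientation is ambiguous and the merge refuses,
    listing the loci concerned — flips are never inferred silently.
    """
    shared = [l for l in a.loci if l in set(b.loci)]
    dropped_a = [l for l in a.loci if l not in set(shared)]
    dropped_b = [l for l in b.loci if l not in set(shared)]
    overlap_pops = set(a.populations) & set(b.populations)
    if overlap_pops:
        raise ValueError(f"population names collide: {sorted(overlap_pops)}")
    if not shared:
        empty = AlleleFrequencyTable(
            pd.DataFrame(
                np.empty((0, a.n_pops + b.n_pops)),
                columns=a.populations + b.populations,
            ),
            pd.concat([a.n_individuals, b.n_individuals]),
        )
        return empty, MergeReport([], dropped_a, dropped_b)
    if allele_key is None:
        raise ValueError(
            "allele orientation key required; ambiguous loci: "
            f"{shared[:10]}{'...' if len(shared) > 10 else ''}"
        )
    if isinstance(allele_key, str):
        if allele_key not in ("same", "flip"):
            raise ValueError("allele_key string must be 'same' or 'flip'")
        key = {l: allele_key for l in shared}
    else:
        missing = [l for l in shared if l not in allele_key]
        if missing:
            raise ValueError(f"allele_key missing loci: {missing[:10]}")
        key = allele_key
    b_freq = b.freq.loc[shared].copy()
    flipped = []
    for locus in shared:
        action = key[locus]
        if action == "flip":
            b_freq.loc[locus] = 1.0 - b_freq.loc[locus]
            flipped.append(locus)
        elif action != "same":
            raise ValueError(f"allele_key[{locus!r}] must be 'same' or 'flip'")
    merged = pd.concat([a.freq.loc[shared], b_freq], axis=1)
    sizes = pd.concat([a.n_individuals, b.n_individuals])
    return (
        AlleleFrequencyTable(merged, sizes),
        MergeReport(shared, dropped_a, dropped_b, flipped),
    )
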