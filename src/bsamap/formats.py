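"""File formats: PoPoolation2 sync, BED6/GFF3 gene annotations, gene-to-GO
maps, haplotype panels (TSV and minimal VCF) and commented result tables.

Internal coordinates are 1-based inclusive everywhere; BED's half-open
0-based intervals are converted on ingest and egress.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, FormatError, ParseError
from .genome import Arm
from .popgen import HaplotypePanel

GO_RE = re.compile(r"^GO:\d{7}$")

#: sync count-column order
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")


@dataclass(frozen=True)
class SyncSite:
    """One line of a sync file: per-pool read counts in A:T:C:G:N:del order."""

    arm: str
    pos: int
    ref: str
    counts_per_pool: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"{self.arm}:{self.pos}: positions are 1-based")
        for counts in self.counts_per_pool:
            if len(counts) != 6 or any(c < 0 for c in counts):
                raise FormatError(
                    f"{self.arm}:{self.pos}: pool counts must be 6 non-negative integers"
                )


def read_sync(path, min_pools: int = 1) -> list[SyncSite]:
    """Parse a sync file; every line must carry the same number of pools
    (and at least ``min_pools``)."""
    sites: list[SyncSite] = []
    n_pools: int | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 + min_pools:
                raise ParseError(
                    f"expected at least {3 + min_pools} tab-separated fields, "
                    f"got {len(fields)}",
                    line_no,
                )
            arm, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"position {pos_s!r} is not an integer", line_no)
            pools = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ParseError(
                        f"count field {col!r} must have 6 ':'-separated integers",
                        line_no,
                    )
                try:
                    pools.append(tuple(int(p) for p in parts))
                except ValueError:
                    raise ParseError(f"non-integer count in field {col!r}", line_no)
            if n_pools is None:
                n_pools = len(pools)
            elif len(pools) != n_pools:
                raise FormatError(
                    f"line {line_no}: {len(pools)} pools but earlier lines have {n_pools}"
                )
            try:
                sites.append(SyncSite(arm, pos, ref, tuple(pools)))
            except FormatError as err:
                raise ParseError(str(err), line_no)
    return sites


def write_sync(sites, path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            pools = "\t".join(":".join(str(c) for c in p) for p in s.counts_per_pool)
            fh.write(f"{s.arm}\t{s.pos}\t{s.ref}\t{pools}\n")


# ---------------------------------------------------------------------------
# gene annotations


def read_annotation(path, dialect: str) -> pd.DataFrame:
    """Gene spans as a table (gene_id, arm, start, end, strand), 1-based
    inclusive.  BED6 is converted from half-open 0-based; from GFF3 only
    records of type "gene" are retained."""
    if dialect == "BED":
        return _read_bed(path)
    if dialect == "GFF3":
        return _read_gff3(path)
    raise ConfigError(f"unknown annotation dialect {dialect!r} (use BED or GFF3)")


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError("BED gene lines need at least 4 columns", line_no)
            arm, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) >= 6 else "+"
            start, end = start0 + 1, end0  # half-open 0-based -> closed 1-based
            if end < start:
                raise FormatError(f"line {line_no}: empty or inverted interval")
            rows.append((name, arm, start, end, strand))
    return _gene_frame(rows)


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError("GFF3 lines need 9 columns", line_no)
            if f[2] != "gene":
                continue
            start, end = int(f[3]), int(f[4])
            if end < start:
                raise FormatError(f"line {line_no}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise ParseError("gene record lacks an ID attribute", line_no)
            rows.append((gene_id, f[0], start, end, f[6]))
    return _gene_frame(rows)


def _gene_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r}")
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples():
            fh.write(
                f"{g.arm}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# GO maps


def read_go_map(path) -> dict[str, set[str]]:
    """Gene -> GO-term-set from a two-column TSV or a GAF-like file
    (columns 2 and 5).  Rows whose term fails the GO:0000000 syntax are
    skipped with a warning; duplicates merge."""
    go: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            f = line.split("\t")
            if len(f) >= 5 and GO_RE.match(f[4]):
                gene, term = f[1], f[4]
            elif len(f) >= 2:
                gene, term = f[0], f[1]
            else:
                raise ParseError("need at least 2 tab-separated columns", line_no)
            if not GO_RE.match(term):
                warnings.warn(f"line {line_no}: {term!r} is not a GO id; row skipped")
                continue
            go.setdefault(gene, set()).add(term)
    return go


def write_go_map(go: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go):
            for term in sorted(go[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# haplotype panels


def write_panel_tsv(panel: HaplotypePanel, path) -> None:
    """Haplotype matrix TSV: arm, pos, then one 0/1 column per haplotype
    (column names <label>_h<i>)."""
    frames = []
    cols1 = [f"{panel.labels[0]}_h{i}" for i in range(panel.n1)]
    cols2 = [f"{panel.labels[1]}_h{i}" for i in range(panel.n2)]
    for arm in panel.arms:
        a = arm.name
        df = pd.DataFrame(
            np.hstack([panel.pop1[a].T, panel.pop2[a].T]).astype(int),
            columns=cols1 + cols2,
        )
        df.insert(0, "pos", panel.positions[a].astype(int))
        df.insert(0, "arm", a)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, arms: tuple[Arm, ...], labels=("pop1", "pop2")) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    cols1 = [c for c in df.columns if c.startswith(labels[0] + "_h")]
    cols2 = [c for c in df.columns if c.startswith(labels[1] + "_h")]
    if not cols1 or not cols2:
        raise FormatError("panel TSV must contain <label>_h<i> haplotype columns")
    positions, pop1, pop2 = {}, {}, {}
    by_name = {a.name: a for a in arms}
    for a, sub in df.groupby("arm", sort=False):
        if a not in by_name:
            raise FormatError(f"panel arm {a!r} not in the configured arm set")
        positions[a] = sub["pos"].to_numpy()
        pop1[a] = sub[cols1].to_numpy().T.astype(np.uint8)
        pop2[a] = sub[cols2].to_numpy().T.astype(np.uint8)
    used = tuple(by_name[a] for a in positions)
    return HaplotypePanel(used, positions, pop1, pop2, labels=tuple(labels))


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Minimal phased VCF (haplotypes paired into pseudo-diploids; both
    panels must have even haplotype counts)."""
    if panel.n1 % 2 or panel.n2 % 2:
        raise ConfigError("VCF export needs even haplotype counts; use the TSV format")
    samples = [f"{panel.labels[0]}_{i}" for i in range(panel.n1 // 2)] + [
        f"{panel.labels[1]}_{i}" for i in range(panel.n2 // 2)
    ]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for arm in panel.arms:
            fh.write(f"##contig=<ID={arm.name},length={arm.length_bp}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for arm in panel.arms:
            a = arm.name
            h = np.vstack([panel.pop1[a], panel.pop2[a]])
            for j, pos in enumerate(panel.positions[a]):
                gts = [
                    f"{h[2 * k, j]}|{h[2 * k + 1, j]}" for k in range(h.shape[0] // 2)
                ]
                fh.write(
                    f"{a}\t{int(pos)}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


def read_panel_vcf(path, arms: tuple[Arm, ...], n1: int, labels=("pop1", "pop2")) -> HaplotypePanel:
    """Read a phased VCF back into a panel; the first ``n1`` haplotypes
    (sample order x 2) form population 1."""
    from cyvcf2 import VCF

    by_name = {a.name: a for a in arms}
    positions: dict[str, list[int]] = {}
    haps: dict[str, list[np.ndarray]] = {}
    vcf = VCF(str(path))
    for rec in vcf:
        a = rec.CHROM
        if a not in by_name:
            raise FormatError(f"VCF contig {a!r} not in the configured arm set")
        gt = np.array(rec.genotypes)[:, :2].ravel().astype(np.uint8)
        positions.setdefault(a, []).append(rec.POS)
        haps.setdefault(a, []).append(gt)
    pos_arr, pop1, pop2 = {}, {}, {}
    for a in positions:
        mat = np.array(haps[a]).T  # haplotype x site
        pos_arr[a] = np.asarray(positions[a])
        pop1[a] = mat[:n1]
        pop2[a] = mat[n1:]
    used = tuple(by_name[a] for a in pos_arr)
    return HaplotypePanel(used, pos_arr, pop1, pop2, labels=tuple(labels))


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path, name: str = "table") -> None:
    """TSV with a commented header naming the columns and tool version."""
    with open(path, "w") as fh:
        fh.write(f"# bsamap {__version__} {name}; columns: {', '.join(df.columns)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
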