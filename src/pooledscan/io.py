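"""File formats, configuration, the validated-loci fixture, and reports.

TSV dialect everywhere: UTF-8, tab-separated, '.' for missing, mandatory
headers, no quoting.  Genotypes round-trip through TSV (one dosage column
per individual, header ``<id>:<group>``) or a minimal VCF 4.2; blocks are
exported as BED (0-based half-open) plus a member detail TSV.

The packaged fixture ``data/table2.tsv`` transcribes the published table of
loci validated or replicated by individual TaqMan genotyping (GRCh37
coordinates, ORs for minor alleles).  A SHA-256 checksum guards it against
accidental edits; it is data for bookkeeping checks, not ground truth for
the statistics engine.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .allelotyping import QcReport, RasMatrix, ScanResult
from .blocks import Block, Candidate, CandidateSet
from .simulate import (
    EffectLocus,
    GenotypeTable,
    IntensityTable,
    PoolSetSpec,
    SimulationSpec,
    SnpDef,
    make_snp_panel,
)
from .validation import SharedLociSummary, ValidationRecord, ContingencyTable

__all__ = [
    "MISSING",
    "Table2Row",
    "Table2Fixture",
    "Table2Summary",
    "load_table2",
    "summarize_table2",
    "parse_pvalue",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "write_intensities_tsv",
    "read_intensities_tsv",
    "write_ras_tsv",
    "read_ras_tsv",
    "write_scan_tsv",
    "read_track_tsv",
    "write_blocks_bed",
    "write_blocks_tsv",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_validation_tsv",
    "load_simulation_spec",
    "dump_simulation_spec",
    "write_report",
]

MISSING = "."
TABLE2_SHA256 = "52e918389e49ba6c0f829560b1d75479644228ff01252f1be008713462aeeb51"

# ---------------------------------------------------------------------------
# Table 2 fixture


@dataclass(frozen=True)
class Table2Row:
    locus: str
    snp_id: str
    position: int
    location: str
    genes: str
    pbc_p: float | None
    pbc_or: float | None
    psc_p: float | None
    psc_or: float | None
    minor_allele: str
    maf: float
    replication_panel: bool


@dataclass
class Table2Fixture:
    rows: list[Table2Row]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Table2Summary:
    total_snps: int
    distinct_loci: int
    pbc_only: int
    psc_only: int
    shared: int
    shared_same_direction: int
    per_locus: dict[str, tuple[int, int, int]]  # locus -> (pbc_only, psc_only, shared)

    def locus_total(self, locus: str) -> int:
        return sum(self.per_locus.get(locus, (0, 0, 0)))


_SCI_RE = re.compile(
    r"^\s*(?P<m>\d+(?:\.\d+)?)\s*[x×]\s*10\s*(?:\^|)\s*(?P<s>[-−])?\s*(?P<e>\d+)\s*$"
)


def parse_pvalue(text: str) -> float | None:
    """Parse a table p-value/OR cell: plain or E-notation floats, or the
    typeset form '1.5 × 10−7' (unicode minus and 'x' both accepted)."""
    s = text.strip()
    if s == MISSING or not s:
        return None
    m = _SCI_RE.match(s)
    if m:
        exp = int(m.group("e"))
        if m.group("s"):
            exp = -exp
        return float(m.group("m")) * 10.0**exp
    return float(s)


def load_table2(path: str | Path | None = None) -> Table2Fixture:
    """Load the packaged validated-loci fixture, verifying its checksum."""
    if path is None:
        ref = resources.files("pooledscan").joinpath("data/table2.tsv")
        raw = ref.read_bytes()
    else:
        raw = Path(path).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise ValueError(
            f"fixture checksum mismatch: expected {TABLE2_SHA256[:12]}..., "
            f"got {digest[:12]}... (fixture edited?)"
        )
    lines = raw.decode("utf-8").splitlines()
    header = lines[0].split("\t")
    rows: list[Table2Row] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = dict(zip(header, line.split("\t")))
        rows.append(
            Table2Row(
                locus=cells["locus"],
                snp_id=cells["snp_id"],
                position=int(cells["position"]),
                location=cells["location"],
                genes=cells["genes"],
                pbc_p=parse_pvalue(cells["pbc_p"]),
                pbc_or=parse_pvalue(cells["pbc_or"]),
                psc_p=parse_pvalue(cells["psc_p"]),
                psc_or=parse_pvalue(cells["psc_or"]),
                minor_allele=cells["minor_allele"],
                maf=float(cells["maf"]),
                replication_panel=cells["replication_panel"] == "yes",
            )
        )
    ids = [r.snp_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("fixture snp_id values are not unique")
    for r in rows:
        if r.pbc_p is None and r.psc_p is None:
            raise ValueError(f"{r.snp_id}: row has neither disease column")
    return Table2Fixture(rows=rows)


def summarize_table2(fixture: Table2Fixture) -> Table2Summary:
    """Recompute the bookkeeping counts over the fixture: totals, distinct
    locus labels, per-disease uniqueness, and per-locus breakdowns."""
    per_locus: dict[str, list[int]] = {}
    pbc_only = psc_only = shared = shared_same = 0
    for r in fixture.rows:
        has_pbc = r.pbc_p is not None
        has_psc = r.psc_p is not None
        slot = per_locus.setdefault(r.locus, [0, 0, 0])
        if has_pbc and has_psc:
            shared += 1
            slot[2] += 1
            if (r.pbc_or > 1.0) == (r.psc_or > 1.0):
                shared_same += 1
        elif has_pbc:
            pbc_only += 1
            slot[0] += 1
        else:
            psc_only += 1
            slot[1] += 1
    return Table2Summary(
        total_snps=len(fixture.rows),
        distinct_loci=len(per_locus),
        pbc_only=pbc_only,
        psc_only=psc_only,
        shared=shared,
        shared_same_direction=shared_same,
        per_locus={k: tuple(v) for k, v in per_locus.items()},
    )


# ---------------------------------------------------------------------------
# Genotypes


def write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cols = [f"{iid}:{grp}" for iid, grp in table.individuals]
        fh.write("\t".join(["snp_id", "chrom", "pos", "alleles"] + cols) + "\n")
        for j, snp in enumerate(table.snp_panel):
            dosages = [
                MISSING if v < 0 else str(int(v)) for v in table.genotypes[:, j]
            ]
            fh.write(
                "\t".join(
                    [snp.snp_id, snp.chrom, str(snp.pos), f"{snp.allele_a}/{snp.allele_b}"]
                    + dosages
                )
                + "\n"
            )


def read_genotypes_tsv(path: str | Path, mafs: Mapping[str, float] | None = None) -> GenotypeTable:
    """Read a dosage TSV back into a GenotypeTable.

    Control MAFs are not stored in the TSV; supply ``mafs`` to restore them,
    otherwise they are recomputed as 0 placeholders are avoided by using the
    observed frequency capped at 0.5.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        id_cols = header[4:]
        individuals = [tuple(c.split(":", 1)) for c in id_cols]
        panel: list[SnpDef] = []
        rows: list[list[int]] = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            a1, a2 = cells[3].split("/")
            dosages = [-1 if c == MISSING else int(c) for c in cells[4:]]
            obs = [d for d in dosages if d >= 0]
            freq = sum(obs) / (2.0 * len(obs)) if obs else 0.0
            maf = (
                mafs[cells[0]]
                if mafs is not None and cells[0] in mafs
                else min(freq, 1.0 - freq)
            )
            panel.append(
                SnpDef(
                    snp_id=cells[0], chrom=cells[1], pos=int(cells[2]),
                    allele_a=a1, allele_b=a2, maf=maf,
                )
            )
            rows.append(dosages)
    geno = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(individuals), 0), np.int8)
    return GenotypeTable(
        individuals=[(i, g) for i, g in individuals], genotypes=geno, snp_panel=panel
    )


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT fields; allele_b is REF, allele_a ALT, dosage
    counts ALT copies."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pooledscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in table.snp_panel):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = [iid for iid, _ in table.individuals]
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j, snp in enumerate(table.snp_panel):
            gts = [gt_map[int(v)] for v in table.genotypes[:, j]]
            fh.write(
                "\t".join(
                    [snp.chrom, str(snp.pos), snp.snp_id, snp.allele_b, snp.allele_a,
                     ".", "PASS", ".", "GT"] + gts
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Intensities and RAS


def _panel_header(panel: Sequence[SnpDef], paired: bool) -> list[str]:
    if paired:
        cols: list[str] = []
        for s in panel:
            cols.extend([f"{s.snp_id}.A", f"{s.snp_id}.B"])
        return cols
    return [s.snp_id for s in panel]


def write_intensities_tsv(table: IntensityTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "\t".join(["pool_id", "group", "set_id"] + _panel_header(table.snp_panel, True))
            + "\n"
        )
        for i, (pid, grp, sid) in enumerate(table.pools):
            cells = [pid, grp, sid]
            for j in range(len(table.snp_panel)):
                cells.append(repr(float(table.channel_a[i, j])))
                cells.append(repr(float(table.channel_b[i, j])))
            fh.write("\t".join(cells) + "\n")


def read_intensities_tsv(
    path: str | Path, panel: Sequence[SnpDef] | None = None
) -> IntensityTable:
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"pool_id": str, "group": str, "set_id": str},
    )
    snp_ids = [c[:-2] for c in df.columns[3:] if c.endswith(".A")]
    if panel is None:
        panel = [
            SnpDef(snp_id=s, chrom="0", pos=i + 1, allele_a="A", allele_b="B", maf=0.0)
            for i, s in enumerate(snp_ids)
        ]
    a = df[[f"{s}.A" for s in snp_ids]].to_numpy(dtype=float)
    b = df[[f"{s}.B" for s in snp_ids]].to_numpy(dtype=float)
    pools = list(zip(df["pool_id"], df["group"], df["set_id"]))
    return IntensityTable(pools=pools, channel_a=a, channel_b=b, snp_panel=list(panel))


def write_ras_tsv(ras: RasMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "\t".join(["pool_id", "group", "set_id"] + _panel_header(ras.snp_index, False))
            + "\n"
        )
        for i, (pid, grp, sid) in enumerate(ras.pools):
            cells = [pid, grp, sid]
            for j in range(len(ras.snp_index)):
                cells.append(MISSING if ras.missing[i, j] else repr(float(ras.values[i, j])))
            fh.write("\t".join(cells) + "\n")


def read_ras_tsv(path: str | Path, panel: Sequence[SnpDef] | None = None) -> RasMatrix:
    df = pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False,
        float_precision="round_trip",
        dtype={"pool_id": str, "group": str, "set_id": str},
    )
    snp_ids = list(df.columns[3:])
    if panel is None:
        panel = [
            SnpDef(snp_id=s, chrom="0", pos=i + 1, allele_a="A", allele_b="B", maf=0.0)
            for i, s in enumerate(snp_ids)
        ]
    values = df[snp_ids].to_numpy(dtype=float)
    pools = list(zip(df["pool_id"], df["group"], df["set_id"]))
    return RasMatrix(
        pools=pools, values=values, missing=np.isnan(values), snp_index=list(panel)
    )


# ---------------------------------------------------------------------------
# Scan results and tracks


def write_scan_tsv(
    results: Sequence[ScanResult], snp_index: Sequence[SnpDef], path: str | Path
) -> None:
    pos = {s.snp_id: (s.chrom, s.pos) for s in snp_index}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "snp_id\tchrom\tpos\tset_id\tmean_ras_case\tmean_ras_control\t"
            "t\tdf\tp_value\tp_bonferroni\tdirection\tn_case_pools\t"
            "n_control_pools\tskipped\n"
        )
        for r in results:
            chrom, bp = pos[r.snp_id]
            fh.write(
                "\t".join(
                    [
                        r.snp_id, chrom, str(bp), r.set_id,
                        repr(r.mean_ras_case), repr(r.mean_ras_control),
                        repr(r.t_stat), repr(r.df), repr(r.p_value),
                        repr(r.p_bonferroni), str(r.direction),
                        str(r.n_case_pools), str(r.n_control_pools),
                        "yes" if r.skipped else "no",
                    ]
                )
                + "\n"
            )


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    """Read a scan TSV (or minimal chrom/pos/snp_id/p_value TSV) as a block
    -finding track."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    need = {"chrom", "pos", "snp_id", "p_value"}
    if not need.issubset(df.columns):
        raise ValueError(f"track file must have columns {sorted(need)}")
    return df[["chrom", "pos", "snp_id", "p_value"]]


# ---------------------------------------------------------------------------
# Blocks, candidates, validation records


def write_blocks_bed(blocks: Sequence[Block], path: str | Path) -> None:
    """BED intervals for blocks: 0-based half-open, start = start_pos - 1,
    end = end_pos (so end - start = span + 1 in 1-based inclusive terms)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, b in enumerate(blocks):
            fh.write(f"{b.chrom}\t{b.start_pos - 1}\t{b.end_pos}\tblock_{i + 1}\t{b.n_members}\n")


def write_blocks_tsv(blocks: Sequence[Block], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("block\tchrom\tpos\tsnp_id\tp_value\tis_index\tindex_rank\n")
        for i, b in enumerate(blocks):
            ranks = {sid: rank for sid, _, _, rank in b.index_snps}
            for sid, bp, pv in b.member_snps:
                rank = ranks.get(sid)
                fh.write(
                    f"block_{i + 1}\t{b.chrom}\t{bp}\t{sid}\t{pv!r}\t"
                    f"{'yes' if rank else 'no'}\t{rank if rank else MISSING}\n"
                )


def write_candidates_tsv(cset: CandidateSet, path: str | Path) -> None:
    rounds = sorted({r for c in cset.candidates.values() for r in c.rounds_found})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "snp_id\tchrom\tpos\tdisease\trounds_found\t"
            + "\t".join(f"best_p_round_{r}" for r in rounds)
            + "\n"
        )
        for c in sorted(cset.candidates.values(), key=lambda c: c.snp_id):
            cells = [
                c.snp_id, c.chrom, str(c.pos), cset.disease,
                ",".join(sorted(c.rounds_found)),
            ]
            for r in rounds:
                pv = c.best_p_per_round.get(r)
                cells.append(MISSING if pv is None else repr(pv))
            fh.write("\t".join(cells) + "\n")


def read_candidates_tsv(path: str | Path) -> CandidateSet:
    df = pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False,
        float_precision="round_trip",
        dtype={"snp_id": str, "chrom": str, "disease": str, "rounds_found": str},
    )
    disease = str(df["disease"].iloc[0]) if len(df) else "UNKNOWN"
    round_cols = [c for c in df.columns if c.startswith("best_p_round_")]
    cands: dict[str, Candidate] = {}
    for _, row in df.iterrows():
        best = {
            c[len("best_p_round_"):]: float(row[c])
            for c in round_cols
            if not pd.isna(row[c])
        }
        cands[row["snp_id"]] = Candidate(
            snp_id=row["snp_id"],
            rounds_found=frozenset(row["rounds_found"].split(",")),
            best_p_per_round=best,
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
        )
    return CandidateSet(disease=disease, candidates=cands)


def write_validation_tsv(recs: Sequence[ValidationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "snp_id\tdisease\ta\tb\tc\td\tfisher_p\tor\tci_low\tci_high\t"
            "maf_controls\ttier\tdirection_concordant\n"
        )
        for r in recs:
            conc = (
                MISSING
                if r.direction_concordant_with_gwas is None
                else ("yes" if r.direction_concordant_with_gwas else "no")
            )
            t = r.table
            fh.write(
                "\t".join(
                    [
                        r.snp_id, r.disease, str(t.a), str(t.b), str(t.c), str(t.d),
                        repr(r.fisher_p), repr(r.or_point), repr(r.ci_low),
                        repr(r.ci_high), repr(r.maf_controls), r.tier, conc,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Configuration


def _spec_to_dict(spec: SimulationSpec) -> dict[str, Any]:
    return {
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "ld_block_length": spec.ld_block_length,
        "ld_r": spec.ld_r,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "case_group": spec.case_group,
        "control_group": spec.control_group,
        "reuse_across_sets": spec.reuse_across_sets,
        "effect_loci": [
            {"snp_id": e.snp_id, "odds_ratio": e.odds_ratio, "disease": e.disease}
            for e in spec.effect_loci
        ],
        "pool_sets": [
            {
                "set_id": p.set_id,
                "pool_size": p.pool_size,
                "pools_per_group": dict(p.pools_per_group),
                **({"pool_sizes": dict(p.pool_sizes)} if p.pool_sizes else {}),
            }
            for p in spec.pool_sets
        ],
        "snp_panel": [
            {
                "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
                "allele_a": s.allele_a, "allele_b": s.allele_b, "maf": s.maf,
            }
            for s in spec.snp_panel
        ],
    }


def dump_simulation_spec(spec: SimulationSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def load_simulation_spec(path: str | Path) -> SimulationSpec:
    """Load a simulation spec from YAML.

    The panel is given either inline under ``snp_panel`` or generated from a
    ``panel`` stanza (n_snps, block_length, spacing_bp, maf_range, seed...)
    forwarded to :func:`pooledscan.simulate.make_snp_panel`.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if "snp_panel" in cfg:
        panel = tuple(SnpDef(**row) for row in cfg.pop("snp_panel"))
        cfg.pop("panel", None)
    elif "panel" in cfg:
        stanza = dict(cfg.pop("panel"))
        n_snps = stanza.pop("n_snps")
        seed = stanza.pop("seed", cfg.get("seed", 0))
        panel = make_snp_panel(n_snps, rng=seed, **stanza)
    else:
        raise ValueError("config needs either 'snp_panel' or 'panel'")
    effect_loci = tuple(EffectLocus(**row) for row in cfg.pop("effect_loci", []))
    pool_sets = tuple(PoolSetSpec(**row) for row in cfg.pop("pool_sets", []))
    return SimulationSpec(
        snp_panel=panel, effect_loci=effect_loci, pool_sets=pool_sets, **cfg
    )


# ---------------------------------------------------------------------------
# Report


def write_report(
    outdir: str | Path,
    config: Mapping[str, Any],
    *,
    qc: Mapping[str, QcReport] | None = None,
    scans: Mapping[str, Sequence[ScanResult]] | None = None,
    blocks: Mapping[str, Sequence[Block]] | None = None,
    candidates: CandidateSet | None = None,
    validation: Sequence[ValidationRecord] | None = None,
    shared: SharedLociSummary | None = None,
    table2_summary: Table2Summary | None = None,
    n_tests: int | None = None,
) -> Path:
    """Write the human-readable run report plus machine-readable TSVs.

    Missing stages are reported as explicit gaps; the resolved configuration
    (including the seed) is embedded so reruns are reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# pooledscan run report", ""]
    lines.append("## Configuration")
    lines.append("```yaml")
    lines.append(yaml.safe_dump(dict(config), sort_keys=False).rstrip())
    lines.append("```")

    lines.append("\n## Pool QC")
    if qc is None:
        lines.append("(stage not run)")
    else:
        for set_id, rep in qc.items():
            lines.append(
                f"- set {set_id}: retained {len(rep.retained_pools)}, "
                f"removed {len(rep.removed_pools)} "
                f"(threshold {rep.threshold_used})"
            )
            for pid, reason, score in rep.removed_pools:
                lines.append(f"  - removed {pid}: {reason} (z = {score:.2f})")

    lines.append("\n## Pooled scan")
    if scans is None:
        lines.append("(stage not run)")
    else:
        for set_id, results in scans.items():
            tested = [r for r in results if not r.skipped]
            lines.append(
                f"- set {set_id}: {len(results)} SNPs, {len(tested)} tested, "
                f"min p = {min((r.p_value for r in tested), default=float('nan')):.3g}"
            )

    lines.append("\n## Blocks and candidates")
    if blocks is None:
        lines.append("(stage not run)")
    else:
        for set_id, bl in blocks.items():
            n_index = sum(len(b.index_snps) for b in bl)
            lines.append(f"- set {set_id}: {len(bl)} blocks, {n_index} index SNPs")
    if candidates is not None:
        lines.append(f"- merged candidates ({candidates.disease}): {len(candidates)}")
        write_candidates_tsv(candidates, outdir / "candidates.tsv")
        if len(candidates) == 0:
            lines.append("- zero candidates selected")

    lines.append("\n## Validation")
    if validation is None:
        lines.append("(stage not run)")
    else:
        nt = n_tests if n_tests is not None else max(1, len(validation))
        lines.append(
            f"- {len(validation)} candidates tested; Bonferroni threshold "
            f"0.05/{nt} = {0.05 / nt:.2g}"
        )
        for tier in ("corrected", "suggestive", "not_validated"):
            k = sum(1 for r in validation if r.tier == tier)
            lines.append(f"  - {tier}: {k}")
        write_validation_tsv(validation, outdir / "validation.tsv")

    if shared is not None:
        lines.append("\n## Cross-disease shared loci")
        lines.append(
            f"- unique to disease 1: {len(shared.unique_disease1)}; "
            f"unique to disease 2: {len(shared.unique_disease2)}; "
            f"shared: {len(shared.shared)} "
            f"(same direction: {len(shared.shared_same_direction)})"
        )

    if table2_summary is not None:
        s = table2_summary
        lines.append("\n## Published-table bookkeeping")
        lines.append(
            f"- {s.total_snps} SNPs over {s.distinct_loci} loci; "
            f"{s.pbc_only} PBC-only, {s.psc_only} PSC-only, {s.shared} shared "
            f"({s.shared_same_direction} same direction)"
        )

    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n", encoding="utf-8")
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
    return report
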