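"""End-to-end orchestration: registry + structure dir -> summary report.

Every stage writes plain-text TSV artifacts under the output directory; the
report object keeps the in-memory results.  Every registry entry appears
either in the result tables or in the warning log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from s1scape.composition import disorder_content, kruskal_wallis
from s1scape.flex import bfactor_zscores, read_fluctuation_table
from s1scape.phylo import TreeNode, distance_from_identity, upgma_tree
from s1scape.registry import Registry, kingdom_partition
from s1scape.seqcompare import IdentityReport, ScoringScheme, identity_matrix
from s1scape.structcompare import RmsdMatrix, multiple_superpose, radius_of_gyration
from s1scape.structure import Structure, parse_structure, slice_domain

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "alignment"
    conservation_threshold: float = 0.8
    include_moderate: bool = False
    fluctuation_dir: str | None = None

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.matrix_name, self.gap_open, self.gap_extend)

    def as_text(self) -> str:
        lines = [f"{key} = {val}" for key, val in vars(self).items() if val is not None]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        casts = {
            "gap_open": float,
            "gap_extend": float,
            "conservation_threshold": float,
            "include_moderate": lambda v: v.lower() in ("1", "true", "yes"),
        }
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = casts.get(key, str)(val)
        return cls(**kwargs)


@dataclass
class SummaryReport:
    per_entry: pd.DataFrame
    identity: dict[str, IdentityReport]
    rmsd: dict[str, RmsdMatrix]
    kw: dict[str, object]
    tree: TreeNode | None
    config: PipelineConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_rg(self) -> float:
        return float(self.per_entry["rg"].mean())


def structure_path(structure_dir: Path, pdb_id: str) -> Path | None:
    for name in (f"{pdb_id}.pdb", f"{pdb_id.upper()}.pdb", f"pdb{pdb_id}.ent"):
        p = structure_dir / name
        if p.exists():
            return p
    return None


def load_domains(reg: Registry, structure_dir: str | Path) -> dict[str, Structure]:
    """Parse and slice every registry entry; missing files raise listing ids."""
    structure_dir = Path(structure_dir)
    missing = [r.pdb_id for r in reg if structure_path(structure_dir, r.pdb_id) is None]
    if missing:
        raise FileNotFoundError(
            f"missing structure files in {structure_dir}: {', '.join(sorted(set(missing)))}"
        )
    domains = {}
    for rec in reg:
        full = parse_structure(structure_path(structure_dir, rec.pdb_id), rec.chain_id)
        domains[rec.label] = slice_domain(full, rec.start_res, rec.end_res)
    return domains


def run_pipeline(
    reg: Registry,
    structure_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SummaryReport:
    if len(reg) == 0:
        raise ValueError("empty registry")
    config = config or PipelineConfig()
    sc = config.scoring
    domains = load_domains(reg, structure_dir)
    warnings: list[str] = []

    # per-entry table: sequence, length, Rg, disorder %, flexibility
    rows = []
    for rec in reg:
        dom = domains[rec.label]
        seq = dom.sequence
        if len(seq) < 40 or len(seq) > 120:
            warnings.append(
                f"{rec.label}: domain length {len(seq)} outside the expected band"
            )
        row = {
            "label": rec.label,
            "kingdom": rec.kingdom,
            "protein": rec.protein_name,
            "length": len(seq),
            "rg": radius_of_gyration(dom),
            "disorder_pct": disorder_content(seq),
        }
        try:
            row["bfactor_pct_flexible"] = bfactor_zscores(dom).percent_flexible
        except ValueError as exc:
            row["bfactor_pct_flexible"] = np.nan
            warnings.append(f"{rec.label}: {exc}")
        row["predicted_pct_flexible"] = np.nan
        if config.fluctuation_dir:
            fpath = Path(config.fluctuation_dir) / f"{rec.label}.flex"
            if fpath.exists():
                prof = read_fluctuation_table(fpath, expected_length=len(seq))
                if prof.warning:
                    warnings.append(prof.warning)
                row["predicted_pct_flexible"] = prof.percent_flexible
            else:
                warnings.append(f"{rec.label}: no fluctuation table {fpath.name}")
        rows.append(row)
    per_entry = pd.DataFrame(rows).set_index("label")

    # identity matrices: global and per kingdom
    seqs = {rec.label: domains[rec.label].sequence for rec in reg}
    groups = {rec.label: rec.same_protein_group for rec in reg}
    identity: dict[str, IdentityReport] = {}
    rmsd: dict[str, RmsdMatrix] = {}
    if len(reg) >= 2:
        identity["all"] = identity_matrix(
            seqs, sc, exclusions=groups, denominator=config.identity_denominator
        )
        rmsd["all"], _ = multiple_superpose(
            {lab: domains[lab] for lab in seqs}, sc
        )
    parts = kingdom_partition(reg)
    for kingdom, recs in parts.items():
        if len(recs) < 2:
            continue
        sub = {r.label: seqs[r.label] for r in recs}
        identity[kingdom] = identity_matrix(
            sub, sc, exclusions=groups, denominator=config.identity_denominator
        )
        rmsd[kingdom], _ = multiple_superpose(
            {r.label: domains[r.label] for r in recs}, sc
        )
    for mat in rmsd.values():
        warnings.extend(mat.warnings)

    # Kruskal-Wallis across kingdoms for Rg, disorder and flexibility
    kw: dict[str, object] = {}
    if len(parts) >= 2:
        for column in ("rg", "disorder_pct", "bfactor_pct_flexible"):
            grouped = [
                per_entry.loc[[r.label for r in recs], column].dropna().to_numpy()
                for recs in parts.values()
            ]
            grouped = [g for g in grouped if g.size]
            if len(grouped) >= 2 and sum(g.size for g in grouped) >= 3:
                try:
                    kw[column] = kruskal_wallis(grouped)
                except ValueError as exc:
                    warnings.append(f"kruskal-wallis ({column}): {exc}")

    # dendrogram from global identity distances
    tree = None
    if "all" in identity:
        rep = identity["all"]
        dist = distance_from_identity(rep.labels, rep.matrix)
        tree = upgma_tree(dist)

    report = SummaryReport(
        per_entry=per_entry,
        identity=identity,
        rmsd=rmsd,
        kw=kw,
        tree=tree,
        config=config,
        warnings=warnings,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: SummaryReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_entry.to_csv(out / "per_entry.tsv", sep="\t")
    for name, rep in report.identity.items():
        pd.DataFrame(rep.matrix, index=rep.labels, columns=rep.labels).to_csv(
            out / f"identity_{name}.tsv", sep="\t"
        )
    for name, mat in report.rmsd.items():
        pd.DataFrame(mat.matrix, index=mat.labels, columns=mat.labels).to_csv(
            out / f"rmsd_{name}.tsv", sep="\t"
        )
    with open(out / "kw.tsv", "w") as fh:
        fh.write("variable\tH\tdf\tp\tgroup_sizes\n")
        for name, res in report.kw.items():
            sizes = ",".join(str(x) for x in res.group_sizes)
            fh.write(f"{name}\t{res.H:.6f}\t{res.df}\t{res.p:.6f}\t{sizes}\n")
    if report.tree is not None:
        (out / "tree.nwk").write_text(report.tree.newick() + "\n")
    (out / "config.txt").write_text(report.config.as_text())
    (out / "warnings.log").write_text(
        "".join(w + "\n" for w in report.warnings) if report.warnings else ""
    )
    _write_summary(report, out / "summary.txt")


def _write_summary(report: SummaryReport, path: Path) -> None:
    """Human-readable digest; identities as whole %, Å values to 0.01."""
    lines = ["s1scape summary", "=" * 40]
    lines.append(f"entries: {len(report.per_entry)}")
    lines.append(f"mean Rg: {report.mean_rg:.2f} A")
    for name, rep in report.identity.items():
        if rep.max_pair:
            a, b, v = rep.max_pair
            lines.append(f"identity[{name}] max: {a}-{b} {v:.0f}%")
        if rep.min_pair:
            a, b, v = rep.min_pair
            lines.append(f"identity[{name}] min: {a}-{b} {v:.0f}%")
    for name, mat in report.rmsd.items():
        lines.append(f"rmsd[{name}] mean pairwise: {mat.mean_pairwise:.2f} A")
    for name, res in report.kw.items():
        lines.append(f"kruskal-wallis[{name}]: H={res.H:.3f} p={res.p:.4f}")
    dis = report.per_entry["disorder_pct"]
    lines.append(f"disorder-promoting content: min {dis.min():.0f}% max {dis.max():.0f}%")
    if report.warnings:
        lines.append(f"warnings: {len(report.warnings)} (see warnings.log)")
    path.write_text("\n".join(lines) + "\n")
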