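"""File writers: tidy CSVs, the run manifest, and genotype exports.

The canonical output is long-format CSV — one row per scenario × replicate ×
generation for trajectories, one row per scenario × generation for summaries
— plus a JSON manifest recording the full configuration, base seed and
package version so a run can be reproduced exactly.

Genotype exports (Genepop and VCF v4.2 with diploid GT fields) let external
population-genetics tools verify the heterozygosity of any population the
simulator produces.  Loci are abstract, so the VCF uses placeholder
coordinates: chromosome "1", positions 1..L, REF/ALT = A/T.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import RunConfig, config_to_dict
from .population import Population
from .scenario import GridResult

__all__ = ["write_outputs", "export_genepop", "export_vcf"]


def write_outputs(result: GridResult, config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Write trajectories.csv, summary.csv and manifest.json; returns the paths."""
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectories": out / "trajectories.csv",
            "summary": out / "summary.csv",
            "manifest": out / "manifest.json",
        }
        result.frame.to_csv(paths["trajectories"], index=False)
        result.summary().to_csv(paths["summary"], index=False)
        manifest = {
            "config": config_to_dict(config),
            "base_seed": config.base_seed,
            "scenario_ids": list(result.specs),
            "invasim_version": __version__,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing run outputs under {out}: {exc}") from exc
    return paths


def export_genepop(pop: Population, path: str | Path, title: str = "invasim export") -> Path:
    """Write a Genepop file (one population, two-digit allele codes 01/02)."""
    path = Path(path)
    lines = [title]
    lines.extend(f"locus_{i + 1}" for i in range(pop.n_loci))
    lines.append("POP")
    for i in range(pop.size):
        genos = " ".join(
            f"{a + 1:02d}{b + 1:02d}" for a, b in pop.genotypes[i]
        )
        lines.append(f"ind_{i + 1} , {genos}")
    path.write_text("\n".join(lines) + "\n")
    return path


def export_vcf(pop: Population, path: str | Path) -> Path:
    """Write a VCF v4.2 with one record per locus and diploid GT calls.

    Placeholder coordinates (chromosome "1", 1-based consecutive positions)
    keep the format valid for downstream tools; allele 0 maps to REF=A,
    allele 1 to ALT=T.
    """
    path = Path(path)
    header = [
        "##fileformat=VCFv4.2",
        f"##source=invasim {__version__}",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"ind_{i + 1}" for i in range(pop.size)),
    ]
    records = []
    for locus in range(pop.n_loci):
        calls = "\t".join(
            f"{pop.genotypes[i, locus, 0]}/{pop.genotypes[i, locus, 1]}"
            for i in range(pop.size)
        )
        records.append(f"1\t{locus + 1}\tsnp_{locus + 1}\tA\tT\t.\t.\t.\tGT\t{calls}")
    path.write_text("\n".join(header + records) + "\n")
    return path
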