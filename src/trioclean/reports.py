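"""Run manifests and plain-file summary reports.

Reports are pure functions of module outputs; regenerating a report from
the same intermediates is byte-identical.  The manifest records inputs (with
checksums), the filter configuration, tool version and seeds, so that every
emitted report can be traced to exactly one run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .filters import ALL_FILTERS, ExclusionAttribution, FilterConfig, exclusion_venn
from .mendel import STATUS_NAMES, MendelSummary, classify_cohort
from .model import GT_NAMES, CohortTable, Trio


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    command: str
    inputs: dict[str, str]          # path -> sha256
    config: dict
    seed: int | None
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, input_paths: list[str | Path],
               config: FilterConfig | dict | None = None,
               seed: int | None = None) -> "RunManifest":
        cfg = config.to_dict() if isinstance(config, FilterConfig) else (config or {})
        return cls(
            command=command,
            inputs={str(p): _sha256(p) for p in input_paths if Path(p).exists()},
            config=cfg,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def verdict_table(cohort: CohortTable, trio: Trio) -> pd.DataFrame:
    """Per-site Mendelian verdict rows (the TSV layout of the mendel report)."""
    status = classify_cohort(cohort, trio)
    ic, ifa, imo = cohort.trio_indices(trio)
    return pd.DataFrame({
        "chrom": [k.chrom for k in cohort.sites],
        "pos": [k.pos for k in cohort.sites],
        "ref": [k.ref for k in cohort.sites],
        "alt": [k.alt for k in cohort.sites],
        "child_gt": [GT_NAMES[int(g)] for g in cohort.gt[:, ic]],
        "father_gt": [GT_NAMES[int(g)] for g in cohort.gt[:, ifa]],
        "mother_gt": [GT_NAMES[int(g)] for g in cohort.gt[:, imo]],
        "status": [STATUS_NAMES[int(s)] for s in status],
    })


def venn_table(attribution: ExclusionAttribution) -> pd.DataFrame:
    """Seven-region exclusion Venn as a TSV-ready table."""
    regions = exclusion_venn(attribution)
    rows = []
    for members, count in sorted(regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        rows.append({"filters": "+".join(sorted(members)), "n_genotypes_excluded": count})
    rows.append({"filters": "total",
                 "n_genotypes_excluded": sum(regions.values())})
    return pd.DataFrame(rows)


def mendel_summary_block(before: MendelSummary, after: MendelSummary | None = None) -> str:
    """Human-readable ME summary, before and (optionally) after filtering."""
    lines = [
        "Mendelian error summary",
        f"  sites evaluated:        {before.n_sites_evaluated}",
        f"  child called variants:  {before.n_child_variants}",
        f"  Mendelian errors:       {before.n_errors} "
        f"(of which inferred: {before.n_inferred})",
        f"  not evaluable:          {before.n_not_evaluable}",
        f"  ME rate:                {before.error_rate_percent:.2f}%"
        + ("" if before.rate_defined else " (no child calls; reported as 0)"),
    ]
    if after is not None:
        removed = before.n_errors - after.n_errors
        pct = 100.0 * removed / before.n_errors if before.n_errors else 0.0
        lines += [
            "After filtering:",
            f"  child called variants:  {after.n_child_variants}",
            f"  Mendelian errors:       {after.n_errors} "
            f"({pct:.1f}% of errors removed)",
            f"  ME rate:                {after.error_rate_percent:.2f}%",
        ]
    return "\n".join(lines) + "\n"


def summary_report(out_path: str | Path, *,
                   me_before: MendelSummary,
                   me_after: MendelSummary | None = None,
                   attribution: ExclusionAttribution | None = None,
                   concordance: pd.DataFrame | None = None,
                   candidates: pd.DataFrame | None = None) -> None:
    """Single text bundle tying the pipeline stages together.

    Sections are always present; empty stages are reported with zeros
    rather than omitted.
    """
    parts = ["# trioclean summary report", ""]
    parts.append(mendel_summary_block(me_before, me_after))
    parts.append("## Exclusion Venn (genotypes per filter subset)")
    if attribution is not None:
        parts.append(venn_table(attribution).to_csv(sep="\t", index=False))
    else:
        parts.append("(filters not applied)\n")
    parts.append("## Cross-source concordance")
    if concordance is not None and len(concordance):
        parts.append(concordance.to_csv(sep="\t", index=False))
    else:
        parts.append("(single source; no comparison)\n")
    parts.append("## Candidate causative variants")
    if candidates is not None and len(candidates):
        counts = candidates.groupby("model").size()
        for model, n in counts.items():
            parts.append(f"  {model}: {n}")
        parts.append("")
        parts.append(candidates.to_csv(sep="\t", index=False))
    else:
        parts.append("  de_novo: 0\n  recessive_homozygous: 0\n  compound_heterozygous: 0\n")
    Path(out_path).write_text("\n".join(parts))
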