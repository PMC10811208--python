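"""Five-step core-SNP marker selection with a per-step audit trail.

Steps, in order: (1) depth — genotypes below the depth threshold are masked
missing (a strict mode drops loci whose mean depth is below it instead);
(2) completeness — loci called in fewer than the required fraction of
individuals are dropped; (3) MAF; (4) PIC (gene-diversity form 1 - sum fi^2
by default, Botstein form behind the same flag as the diversity module);
(5) genomic location — intergenic loci are dropped, keeping genic loci and
the 5 kb up-/downstream flanks. The filters are conjunctive, so the final
set does not depend on step order, only the per-step counts do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneAnnotation, GenotypeMatrix
from .diversity import locus_stats
from .io import classify_locus_location


@dataclass
class CorePanelReport:
    """Audit trail of core-SNP selection."""

    steps: pd.DataFrame      # step, n_in, n_out
    panel: GenotypeMatrix    # surviving loci
    locus_table: pd.DataFrame  # per-locus maf, pic, location_class

    @property
    def n_core(self) -> int:
        return self.panel.n_loci

    def summary(self) -> str:
        lines = ["Core-SNP selection"]
        for _, row in self.steps.iterrows():
            lines.append(
                f"  {row['step']:<14s} {row['n_in']:>8d} -> {row['n_out']:>8d}"
            )
        lines.append(f"  final core loci: {self.n_core}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "steps": self.steps.to_dict(orient="records"),
            "n_core": self.n_core,
        }


def select_core_snps(
    gm: GenotypeMatrix,
    annotation: GeneAnnotation | None = None,
    min_depth: int = 4,
    min_completeness: float = 0.70,
    min_maf: float = 0.01,
    min_pic: float = 0.4,
    pic_variant: str = "nei",
    flank: int = 5000,
    drop_low_depth_loci: bool = False,
) -> CorePanelReport:
    """Apply the five core-panel filters in order with per-step counts.

    With the default gene-diversity PIC and ``min_pic = 0.4``, every
    surviving biallelic locus necessarily has MAF >= (1 - sqrt(0.2))/... ,
    numerically 0.2764, since max PIC is 0.5 at p = 0.5.
    """
    out = gm.copy()
    steps: list[tuple[str, int, int]] = []

    # (1) depth
    if min_depth is not None:
        if out.D is None:
            raise ValueError("depth filter requires a depth matrix")
        n_in = out.n_loci
        if drop_low_depth_loci:
            with np.errstate(invalid="ignore", divide="ignore"):
                called = out.G >= 0
                mean_depth = np.where(called, out.D, 0).sum(axis=0) / np.maximum(
                    called.sum(axis=0), 1
                )
            out = out.take_loci(mean_depth >= min_depth)
        else:
            out.G[out.D < min_depth] = -1
        steps.append(("depth", n_in, out.n_loci))

    # (2) completeness on the (possibly masked) matrix
    n_in = out.n_loci
    called_frac = (out.G >= 0).mean(axis=0)
    out = out.take_loci(called_frac >= min_completeness)
    steps.append(("completeness", n_in, out.n_loci))

    # (3) MAF
    st = locus_stats(out, pic_variant=pic_variant)
    n_in = out.n_loci
    keep = (st["maf"] >= min_maf) & st["defined"]
    out = out.take_loci(keep.to_numpy())
    steps.append(("maf", n_in, out.n_loci))

    # (4) PIC
    st = locus_stats(out, pic_variant=pic_variant)
    n_in = out.n_loci
    out = out.take_loci((st["pic"] >= min_pic).to_numpy())
    steps.append(("pic", n_in, out.n_loci))

    # (5) location: drop intergenic
    n_in = out.n_loci
    if "location_class" not in out.loci.columns:
        if annotation is None:
            raise ValueError(
                "location filter needs a gene annotation or pre-classified loci"
            )
        out.loci = classify_locus_location(out.loci, annotation, flank=flank)
    out = out.take_loci(
        (out.loci["location_class"] != "intergenic").to_numpy()
    )
    steps.append(("location", n_in, out.n_loci))

    st = locus_stats(out, pic_variant=pic_variant)
    locus_table = out.loci[["chrom", "pos", "ref", "alt", "location_class"]].copy()
    locus_table["maf"] = st["maf"].to_numpy()
    locus_table["pic"] = st["pic"].to_numpy()
    report = pd.DataFrame(steps, columns=["step", "n_in", "n_out"])
    return CorePanelReport(steps=report, panel=out, locus_table=locus_table)


def panel_location_breakdown(report: CorePanelReport) -> pd.DataFrame:
    """Fractions of core loci per location class (sum to 1)."""
    if report.n_core == 0:
        raise ValueError("no core loci")
    frac = (
        report.locus_table["location_class"].value_counts(normalize=True)
        .rename_axis("location_class").reset_index(name="fraction")
    )
    return frac
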