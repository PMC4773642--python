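"""qPCR validation of the microarray: summarize the simulated 12-gene Ct
panel by ΔCt, compare per-gene log2 ratios (Chiquitita vs Arbosana) between
platforms, and group per-sample expression of the top gene by ANOVA + 95% LSD.

Writes results/qpcr_concordance.json and results/qpcr_lsd_grouping.tsv.
"""

import json

import numpy as np
import pandas as pd

from olivearch.io_formats import load_expression
from olivearch.pipeline import qpcr_array_concordance
from olivearch.qpcr import anova_lsd, summarize_ct_table

from common import RESULTS, ensure_bundle


def main() -> None:
    paths = ensure_bundle()
    ct = pd.read_csv(paths["ct_table"], sep="\t")
    matrix = load_expression(paths["expression"])
    summary = summarize_ct_table(ct)

    report = qpcr_array_concordance(summary, matrix, "Chiquitita", "Arbosana",
                                    alpha=0.005, tails=1)
    (RESULTS / "qpcr_concordance.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"platform concordance over {report['n']} genes: "
          f"r = {report['pearson_r']:.3f}, critical value {report['r_critical']:.3f} "
          f"at alpha = {report['alpha']} -> "
          f"{'significant' if report['significant'] else 'not significant'}")

    # per-biological-replicate log2 values of the first panel gene, grouped by sample
    per_bio = summary.attrs["per_biological"]
    gene = report["genes"][0]
    sub = per_bio[per_bio["gene"] == gene]
    groups = {s: g["log2_rel"].to_numpy() for s, g in sub.groupby("sample")}
    grouping = anova_lsd(groups, alpha=0.05)
    frame = grouping.to_frame()
    frame.to_csv(RESULTS / "qpcr_lsd_grouping.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(f"\n{gene}: one-way ANOVA F = {grouping.f_statistic:.2f}, "
          f"p = {grouping.p_value:.3g}; 95% LSD letters:")
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
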