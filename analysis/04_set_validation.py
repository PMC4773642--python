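"""Validate the candidate sets: Kruskal-Wallis against random same-size gene
sets, and Poisson overlap significance between the trait sets.

Reads the candidate table produced by 03_deg_contrasts.py (running it first
if needed) and writes results/set_validation.json.
"""

import json
import subprocess
import sys
from pathlib import Path

from olivearch.io_formats import load_candidate_table, load_expression
from olivearch.pipeline import stage_seed
from olivearch.set_validation import kw_set_validation, poisson_overlap_p

from common import PIPELINE_DIR, RESULTS, SEED, ensure_bundle


def main() -> None:
    paths = ensure_bundle()
    candidates_path = PIPELINE_DIR / "candidates.tsv"
    if not candidates_path.exists():
        subprocess.run([sys.executable, str(Path(__file__).parent / "03_deg_contrasts.py")],
                       check=True)
    matrix = load_expression(paths["expression"])
    sets = load_candidate_table(candidates_path)

    kw_reports = []
    for cs in sets:
        rep = kw_set_validation(matrix, cs.as_set(), n_random=200,
                                seed=stage_seed(SEED, "validate"))
        kw_reports.append({"trait": cs.trait, **rep.to_dict()})
        print(f"{cs.trait}: candidate KW p = {rep.candidate_p:.3g}, "
              f"median random p = {rep.median_random_p:.3f}, "
              f"random sets significant = {rep.fraction_random_significant:.3f}")

    overlaps = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            k = len(a.as_set() & b.as_set())
            rep = poisson_overlap_p(len(a), len(b), matrix.n_genes, k,
                                    label=f"{a.trait}&{b.trait}")
            overlaps.append(rep.to_dict())
            print(f"overlap {rep.label}: k={k}, lambda={rep.expected:.3f}, "
                  f"Poisson P(X>=k)={rep.p_poisson:.4f}")

    out = RESULTS / "set_validation.json"
    out.write_text(json.dumps({"kruskal_wallis": kw_reports, "overlap": overlaps},
                              indent=2) + "\n")
    print(f"\nwritten to {out}")


if __name__ == "__main__":
    main()
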