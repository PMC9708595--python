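#!/usr/bin/env python
"""Cross-frequency convergence of common- and rare-variant enrichment.

Pairs every analysed set's common-variant competitive beta with its burden
beta in each rare class and reports plain Pearson, Spearman and weighted
Pearson correlations (weights 1/(se_a*se_b)), plus the sets FDR-significant
in both arms.  The headline comparison is common vs ultra-rare PTV; the
synonymous classes show what no shared signal looks like.

Reads the arm tables written by scripts 03 and 04; writes
results/05_convergence.tsv and results/05_convergence_pairs.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, make_config  # noqa: E402

from gsconverge.convergence import convergence_report  # noqa: E402
from gsconverge.pipeline_io import FLOAT_FMT  # noqa: E402


def main() -> None:
    warnings.filterwarnings("ignore")
    cfg = make_config()
    common = pd.read_csv(RESULTS / "03_common_enrichment.tsv", sep="\t")
    rare = pd.read_csv(RESULTS / "04_rare_enrichment.tsv", sep="\t")
    common["conditioned_on"] = common["conditioned_on"].fillna("")
    rare["conditioned_on"] = rare["conditioned_on"].fillna("")

    rare_by = {v: sub for v, sub in rare.groupby("variant_class")}
    results, summary = convergence_report(common, rare_by, fdr_q=cfg.fdr_q)
    summary.to_csv(RESULTS / "05_convergence.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)
    pairs = pd.concat([r.table.assign(rare_class=r.pair[1]) for r in results],
                      ignore_index=True)
    pairs.to_csv(RESULTS / "05_convergence_pairs.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)

    print(summary.to_string(index=False))
    urv = summary[summary["rare_class"] == "urv_ptv"].iloc[0]
    print(
        f"\ncommon vs ultra-rare PTV: r = {urv['pearson']:.3f} "
        f"(weighted {urv['weighted_pearson']:.3f}) across {int(urv['n_sets'])} sets; "
        f"synonymous classes sit near zero, as expected for negative controls."
    )


if __name__ == "__main__":
    main()
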