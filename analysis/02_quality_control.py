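"""Apply the study's marker and sample QC to the simulated genotypes.

Filters: individual missingness > 10%, SNP call rate < 95%, MAF < 1%,
Hardy-Weinberg exact-test p < 1e-6, non-autosomal chromosomes.  Writes the
removal accounting to results/qc_report.tsv and prints per-trait descriptive
statistics (n, mean, SD, CV%, SE of the mean).
"""

import merinogp as mg
from common import RESULTS, load_qc_data


def main():
    genos, markers, samples, pheno, report = load_qc_data()
    report.to_frame().to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)
    print(f"QC: {report.n_markers_in} -> {report.n_markers_out} markers, "
          f"{report.n_individuals_in} -> {report.n_individuals_out} individuals")
    for stage, count in report.marker_removals.items():
        print(f"  markers removed at {stage}: {count}")

    stats = mg.descriptive_stats(pheno, ["SL_like", "FER_like"])
    stats.to_csv(RESULTS / "descriptive_stats.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print("\ndescriptive statistics:")
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
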