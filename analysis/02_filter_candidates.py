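"""Filter the synthetic candidate tables.

Runs the three-stage cascade (Poisson LRT + Benjamini-Hochberg at 1% FDR,
ubiquity removal at >=5% in at least half of all samples, persistence
selection at >20% range or >10% peak in at most half a treatment's
samples) on each study and reports how many candidates each stage
removes.  False positives should fall at the BH and ubiquity stages;
lineage hitchhikers and markers should survive.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from evotraj.filtering import filter_pipeline
from evotraj.tables import read_sample_sheet, read_variant_table, write_variant_table


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=pathlib.Path,
                        default=pathlib.Path("results/synthetic"))
    parser.add_argument("--out-dir", type=pathlib.Path,
                        default=pathlib.Path("results/filtered"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for study in ("mouse", "fly"):
        table = read_variant_table(args.in_dir / f"{study}_variants.tsv")
        sheet = read_sample_sheet(args.in_dir / f"{study}_samples.tsv")
        filtered, report = filter_pipeline(table, sheet)
        write_variant_table(filtered, args.out_dir / f"{study}_filtered.tsv")
        report.frame.to_csv(args.out_dir / f"{study}_filter_report.tsv", sep="\t")
        truth = pd.read_csv(args.in_dir / f"{study}_truth.tsv", sep="\t")
        fp_ids = set(truth.loc[truth["is_false_positive"], "mutation_id"])
        kept_fp = sum(mid in fp_ids for mid in filtered.mutation_ids)
        print(f"{study}: {report.stage_counts} "
              f"(false positives surviving: {kept_fp}/{len(fp_ids)})")


if __name__ == "__main__":
    main()
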