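"""Compare per-subject decay constants between compartments.

Liver fat is expected to clear faster than the adipose-tissue volumes.
Runs all six pairwise exact paired Wilcoxon signed-rank tests on the
per-subject decay constants and writes results/decay_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from fatkinetics.stats import compare_decay_constants

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "decay_constants.csv"
    if not path.exists():
        raise SystemExit("run analysis/03_fit_kinetics.py first")
    table = pd.read_csv(path).set_index("subject_id")
    res = compare_decay_constants(table)
    res.to_csv(RESULTS / "decay_comparison.csv", index=False, float_format="%.6g")
    print("pairwise paired Wilcoxon tests on decay constants:")
    print(res.to_string(index=False))
    lf_vat = res[(res["compartment_1"] == "lf_percent") & (res["compartment_2"] == "vat")]
    p = lf_vat["p"].iloc[0]
    print(f"\nliver fat vs VAT: p = {p:.2g} ({'faster' if p < 0.05 else 'not distinguishable'})")


if __name__ == "__main__":
    main()
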