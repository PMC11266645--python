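"""RDM analytics on the ensemble: feature scoring, scenario discovery,
risk curves, trade-offs and temporal risk dynamics.

Writes, under <out>/analysis/: boosted-tree importance shares per
predictor, the successful-scenario subset and its per-policy-bin success
frequencies, binned sustainability/profitability risk curves for the
mid-century (2030-2049), end-of-century (2050-2099) and full periods, the
two highlighted trade-off levels (minimum summed risk; risk ratio nearest
1) and the temporal risk envelopes.

Run:  python analysis/04_rdm_analysis.py [--out results]
"""

import argparse

import pandas as pd

from fishrdm import cli_io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    cfg = cli_io.load_config(args.config) if args.config else cli_io.RunConfig()

    out = cli_io.stage_analyze(cfg, args.out)
    scores = pd.read_csv(out / "feature_scores.csv")
    print("feature-importance shares (gradient-boosted trees):")
    print(scores.pivot_table(index="predictor",
                             columns=["sr_form", "policy_type"],
                             values="importance").round(3).to_string())
    trade = pd.read_csv(out / "tradeoff.csv")
    print("\ntrade-off selections (full period):")
    print(trade[trade["period"] == "full"].round(3).to_string(index=False))
    freq = pd.read_csv(out / "success_frequencies.csv")
    for ptype, grp in freq.groupby("policy_type"):
        first = grp.iloc[0]
        print(f"\n{ptype}: success in lowest policy bin "
              f"(level ~{first['level']:.4g}): {first['success_pct']:.1f}%")


if __name__ == "__main__":
    main()
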