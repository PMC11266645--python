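"""Execute the exploratory-modeling ensemble.

Crosses the sampled stock-recruitment schemes (uniform draws within the
fitted bounds, each with a climate scenario) factorially with the sampled
constant-catch and harvest-rate policies, per SR form, and projects every
run over 2030-2100. At the default scale this is 2 forms x 200 schemes x
100 policies = 40,000 projections. Writes <out>/ensemble/ with the
run-year long table, the per-run summary and the design provenance.

Run:  python analysis/03_run_ensemble.py [--out results] [--quick]
"""

import argparse

import pandas as pd

from fishrdm import cli_io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out", default="results")
    ap.add_argument("--quick", action="store_true",
                    help="reduced scale (20 schemes x 10 policies)")
    args = ap.parse_args()
    cfg = cli_io.load_config(args.config) if args.config else cli_io.RunConfig()
    if args.quick:
        cfg = cfg.model_copy(deep=True)
        cfg.experiment.n_schemes = 20
        cfg.experiment.n_policies = 10

    out = cli_io.stage_run(cfg, args.out)
    summary = pd.read_csv(out / "ensemble_summary.csv")
    print(f"{len(summary)} projection runs written to {out}")
    print(f"successful (both targets met all years): "
          f"{summary['success'].mean() * 100:.1f}%")
    print(f"collapsed at least once: {summary['collapsed'].mean() * 100:.1f}%")
    print(summary.groupby(['sr_form', 'policy_type'])['sustainable_years']
          .mean().rename('mean sustainable years').to_string())


if __name__ == "__main__":
    main()
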