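#!/usr/bin/env python
"""Hazard-increase conditions and the killed-process decomposition.

Verifies that the analytic t=0 conditions (Model 1: mu p_M > lam + kappa;
Model 2: kappa_s Ns > kappa_V NV; Model 3: b > a^2) match the numeric sign
of dh/dt on 1000 random draws per model, and that dh/dt = gain - variance
holds within Monte Carlo error on conditioned ensembles (50 draws).  The
variance term is what usually hides rising tumourigenicity from cohort
hazard curves.  Writes results/hazard_conditions.json.
"""

import argparse
import json
from pathlib import Path

import dormancy.experiments as ex


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/hazard_conditions.json"))
    args = ap.parse_args()

    cond = ex.hazard_condition_agreement(n_draws=1000, seed=args.seed)
    dec = ex.decomposition_identity(n_draws=50, seed=args.seed)

    print(f"t=0 conditions vs numeric sign: {cond['agreement_pct']:.1f}% agreement "
          f"({cond['n_checked']} draws)")
    print(f"decomposition dh/dt = gain - variance: max |z| = {dec['max_abs_z']:.2f}, "
          f"mean |z| = {dec['mean_abs_z']:.2f} over {dec['n_draws']} draws")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({"conditions": cond, "decomposition": dec}, indent=2))


if __name__ == "__main__":
    main()
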