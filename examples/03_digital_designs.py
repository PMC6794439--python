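"""Building the fixed-point circuit's PWL tables and SCM shift-add plans.

Every nonlinear scalar function of the model is tabulated as a continuous
piecewise-linear interpolant with a certified maximum error, and every
multiplication by a model constant becomes a short signed sum of right
shifts (at most 19 bits).  The design serializes to JSON for inspection
or downstream hardware generation.
"""

import astroca as ac

designs = ac.build_designs(dt=1e-3)

print("PWL function tables (certified on a dense grid):")
for name, pf in designs.pwl.items():
    print(f"  {name:12s} domain=[{pf.lo:.3g}, {pf.hi:.3g}] "
          f"segments={pf.n_segments:3d}  max|err|={pf.max_abs_err:.2e}")

print("\nSCM plans for the rate constants:")
for name, plan in designs.const_plans.items():
    terms = " ".join(f"{'+' if s > 0 else '-'}2^-{k}" for s, k in plan.terms)
    print(f"  {name:12s} target={plan.target:<12.6g} terms={len(plan):2d} "
          f"abs_err={plan.abs_err:.2e}  [{terms}]")

plan = ac.scm_decompose(0.018)  # the per-spike 2-AG increment
print(f"\nexample: 0.018 x is realized as {len(plan)} shift-adds, "
      f"error {plan.abs_err:.2e}")
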