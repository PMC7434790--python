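"""Simulate a calibration study and fit the GPCM.

Generates a 404-respondent synthetic dataset from the reference item
parameters of the 12-item Chinese NRSS, fits the generalized partial
credit model by marginal ML, and prints the recovered discrimination
(a), step difficulties (b1..b4), and full-range item information.  The
printed `a` values should track the generating ones (0.33..2.10) within
sampling error, and each item's total information should be close to
the analytic value 4a.
"""

import scaleshort as ss

fixture = ss.make_fixture(ss.SimulationProfile(seed=1))
fit = ss.fit_gpcm(fixture.matrix)

print(f"{'item':5s} {'a_hat':>6s} {'a_true':>7s}   b_hat"
      f"{'':<28s} info")
for iid in fit.item_ids:
    est = fit.params[iid]
    true = fixture.params_ref[iid]
    info = ss.total_item_information(est, "full")
    bs = " ".join(f"{b:6.2f}" for b in est.b)
    print(f"{iid:5s} {est.a:6.2f} {true.a:7.2f}   {bs}   {info:5.2f}")

ti_full = ss.test_information(fit.param_list(), bounds="full")
ti_33 = ss.test_information(fit.param_list(), bounds=(-3, 3))
print(f"\ntest information, entire range: {ti_full:.2f}")
print(f"test information, theta in (-3,3): {ti_33:.2f}")
print(f"Cronbach's alpha: {ss.cronbach_alpha(fixture.matrix):.3f}")
print("\nHigher information means smaller SE of the trait estimate; the")
print("entire-range value is dominated by the high-discrimination items.")
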