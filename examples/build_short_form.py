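"""Construct short forms by both reduction procedures and compare them.

From one simulated 404-person dataset this example (1) walks the
information-based removal trajectory (drop a < 0.4, then least
informative items) until the first substantial test-information drop,
(2) runs the optimal-test-assembly search (branch-and-bound, maximising
information at theta = -3, -1, 0, 1, 3) for the smallest length that
passes the three decision criteria, and (3) tabulates test information,
alpha, and convergent validity of the full and shortened versions.
"""

import scaleshort as ss

fixture = ss.make_fixture(ss.SimulationProfile(seed=3))
fit = ss.fit_gpcm(fixture.matrix, se=False)

traj = ss.iterative_removal(fit)
print("removal trajectory (first TI drop > 7% marks the knee):")
print(traj.to_frame().to_string(
    index=False, float_format=lambda v: f"{v:.2f}"))
print("retained by iterative removal:", ", ".join(traj.retained))

config = ss.OtaConfig()
ota = ss.shortest_satisfying_form(fixture.matrix, config, fit=fit)
print(f"\nOTA short form ({len(ota.items)} items):", ", ".join(ota.items))
print(f"  summed-score corr vs full:  {ota.corr_summed:.3f}  (>= 0.95)")
print(f"  factor-score corr vs full:  {ota.corr_factor:.3f}  (>= 0.95)")
print(f"  convergent: {ota.convergent_summed:.3f} "
      f"(full {ota.convergent_full_summed:.3f}, within 0.05)")
print(f"  alpha: {ota.alpha:.3f} (>= 95% of full {ota.alpha_full:.3f})")

versions = [
    ("full", ss.decision_rules(fit, fixture.matrix,
                               fixture.matrix.item_ids, config)),
    ("ota", ota),
    ("iterative", ss.decision_rules(fit, fixture.matrix,
                                    list(traj.retained), config)),
]
print("\ncomparison (information from each version's own refit):")
print(ss.compare_versions(versions).to_string(
    index=False, float_format=lambda v: f"{v:.2f}"))
print("\nRetention columns give each version's test information as a")
print("percentage of the full form's, over the entire trait range and")
print("over theta in (-3, 3).")
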