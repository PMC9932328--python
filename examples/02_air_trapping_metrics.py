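"""Air-trapping metrics on a paired inspiratory/expiratory lung phantom.

Plants a 10% defect-volume fraction in the right middle lobe of the
expiratory scan and recovers it: A3 (severe trapping under the stringent
patient-specific threshold) should return ~10% in the RML and near zero in
defect-free lobes, while RVC856-950 and E/I MLA sit at their normal-lung
values everywhere else.
"""

from cfqct import TrappingSpec, analyse_pair, make_lobe_mask, make_paired_lung_phantom

mask = make_lobe_mask()
spec = TrappingSpec(defect_fractions={"RML": 0.10}, seed=1)
ph = make_paired_lung_phantom(mask, spec)

print(f"planted RML defect fraction: {ph.realized_fractions['RML']:.4f}")
print(f"{'region':>6} {'TLV cm3':>8} {'RVC':>7} {'E/I MLA':>8} {'A1%':>6} {'A2%':>6} {'A3%':>6}")
for region in ("total", "RUL", "RML", "RLL", "LUL", "LLi", "LLL"):
    r = analyse_pair(ph.insp, ph.mask, ph.exp, ph.mask, region)
    print(f"{region:>6} {r.TLV_cm3:8.1f} {r.RVC:7.3f} {r.EI_MLA:8.3f} "
          f"{r.A1:6.2f} {r.A2:6.2f} {r.A3:6.2f}")
print("\nA3(RML) ~ 10% recovers the planted fraction; the nesting A1 >= A2 >= A3 "
      "holds in every region.")
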