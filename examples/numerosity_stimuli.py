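"""Generate an inverse number/area stimulus series and verify it.

Creates the three-member series in which total element area (TA) varies
exactly opposite to numerosity (n x TA constant, anchored at n=5 with
TA=600 px^2), rasterizes each array, and re-measures it with the
independent flood-fill measurer. The printed measured areas stay within
rasterization tolerance (10%) of the prescribed TA, with exactly n
components each — so number and total area are decoupled across the
series.
"""

from imprintkit import (
    StimulusSpec,
    generate_array,
    inverse_scheme_total_area,
    measure_array,
    save_png,
)

print(f"{'n':>3} {'TA target':>10} {'measured area':>14} {'components':>11}")
for n in (5, 10, 15):
    ta = inverse_scheme_total_area(n, anchor_n=5, anchor_ta=600.0)
    spec = StimulusSpec(n=n, total_area_px2=ta, canvas_w_px=400,
                        canvas_h_px=300, seed=7)
    img = generate_array(spec)
    m = measure_array(img)
    save_png(img, f"numerosity_n{n}.png")
    print(f"{n:>3} {ta:>10.0f} {m.area_px2:>11d} px2 {m.count:>11d}")

print("\nn x TA is constant (3000 px^2) across the series; PNGs and JSON "
      "sidecars written alongside.")
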