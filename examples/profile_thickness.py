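"""Measure glycocalyx thickness from one simulated two-channel line profile.

Builds a lectin/marker profile pair with a known 0.65 µm separation between
the lectin rising edge (outer glycocalyx boundary, at 1.24 µm) and the
marker rising edge (apical membrane, at 1.89 µm), then localizes both
inflection points with the routine polynomial method and the sigmoidal
validation method.
"""

from gcxquant import ProfileSpec, generate_profile_pair, thickness_at_site

spec = ProfileSpec(x_lectin_edge=1.24, thickness_true=0.65, noise_sd=5.0)
lectin, marker, truth = generate_profile_pair(spec, seed=1)

print(f"true edges: lectin {truth.lectin_edge_um:.2f} µm, "
      f"marker {truth.marker_edge_um:.2f} µm (T = {truth.thickness_true:.2f} µm)")
for method in ("polynomial8", "logistic4"):
    m = thickness_at_site(lectin, marker, method=method)
    print(f"{method:12s}: lectin inflection {m.x_inflection_lectin:.3f} µm, "
          f"marker inflection {m.x_inflection_marker:.3f} µm -> T = {m.thickness:.3f} µm")

# The measured T is the inter-inflection distance in µm; with 5% noise both
# methods should land within about one pixel (0.1 µm) of the true 0.65 µm.
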