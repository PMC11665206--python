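"""Simulate a deforming LV phantom and compute its segmental volume curves.

Builds a noise-free left ventricle with an akinetic right-coronary (RCA)
territory, partitions the surface into the 17 AHA segments and prints the
end-diastolic volume of each basal segment plus the total cavity curve.
"""

import numpy as np

from svef3d import PhantomConfig, generate_phantom, volume_curves

cfg = PhantomConfig(rwma_territory="RCA", rwma_severity=0.0, taper_deg=0.0)
seq = generate_phantom(cfg)
traces, total = volume_curves(seq)

print(f"phantom: {len(seq)} frames, {len(seq.frames[0].faces)} faces, "
      f"territory RCA severity {cfg.rwma_severity}")
print(f"total cavity volume: ED {total.volumes.max():.1f} mL -> "
      f"ES {total.volumes.min():.1f} mL")
for sid in range(1, 7):
    v = traces[sid].volumes
    print(f"  basal segment {sid}: ED {v.max():6.2f} mL, swing {np.ptp(v):5.2f} mL")

# Segments 3 and 4 are basal RCA territory: their curves barely move, while
# the normal basal segments each eject roughly half their diastolic volume.
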