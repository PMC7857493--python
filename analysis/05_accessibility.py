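#!/usr/bin/env python
"""Solvent accessibility on toy structures: surface vs core markers and
dimerisation occlusion.

Runs Shrake-Rupley SASA (5 Å probe) on a pseudo-globular cluster with a
surface-placed and a core-placed marker residue, classifies them by
relative accessibility, and quantifies the surface the interface marker
loses when two copies assemble into a contact dimer.
"""

import argparse
from pathlib import Path

from mpoglyco.structure import dimer_occlusion, sequon_accessibility
from mpoglyco.synth import gen_dimer, gen_globular_cluster

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# five independently seeded toy structures stand in for five crystal forms
models = [gen_globular_cluster(n_atoms=60, cluster_radius=8.0, seed=args.seed + i) for i in range(5)]
acc = sequon_accessibility(models, [9001, 9002], probe=5.0, n_points=960)
acc.to_csv(OUT / "marker_accessibility.tsv", sep="\t", index=False)
print(acc.to_string(index=False))

mono = models[0]
marker_x = 8.0 + 2.0 * 1.8
contact = gen_dimer(mono, separation=2.0 * marker_x + 1.0)
apart = gen_dimer(mono, separation=200.0)
occl = dimer_occlusion(mono, contact, [("A", 9001, "ND2")], probe=5.0)
ctrl = dimer_occlusion(mono, apart, [("A", 9001, "ND2")], probe=5.0)
occl.to_csv(OUT / "dimer_occlusion.tsv", sep="\t", index=False)
print(
    f"\ninterface marker SASA loss on dimerisation: "
    f"{occl.loc[0, 'fractional_loss']:.1%} (contact) vs "
    f"{ctrl.loc[0, 'fractional_loss']:.1%} (separated control)"
)
print(f"tables -> {OUT}")
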