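"""Generate a small stratified phantom dataset and inspect its composition.

Writes 20 quarter-scale phantom radiographs with exact landmark ground truth
to ./phantoms_out, then prints the morphology/posture composition and the
spread of the true pelvic incidence.  At n = 500 the default mix reproduces
the emulated study composition (283/101/116 morphologies, 150/200/150
postures) exactly.
"""

from collections import Counter

from spinealign import generate_dataset

images, manifest = generate_dataset(20, seed=7, out_dir="phantoms_out")

print("morphologies:", dict(Counter(e["morphology"] for e in manifest)))
print("postures:    ", dict(Counter(e["posture"] for e in manifest)))

pis = [e["pi"] for e in manifest]
print(f"pelvic incidence across cases: {min(pis):.1f} .. {max(pis):.1f} deg")
print(f"wrote {len(images)} PNGs + landmarks.csv + manifest.yaml "
      f"to ./phantoms_out")
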