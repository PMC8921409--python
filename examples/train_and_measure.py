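"""Train a small cascade on phantoms and measure held-out cases.

Uses a deliberately small training set (40 phantoms, 8 epochs) so the script
finishes in a couple of minutes; accuracy is correspondingly modest.  For
the full desk-scale protocol (200 phantoms, 16 epochs) see the README.
Prints the per-case pelvic tilt against ground truth and the mean landmark
error in pixels.
"""

import numpy as np

from spinealign import (TrainingConfig, compute_all_parameters, desk_profile,
                        generate_dataset, run_cascade, train_cascade)

images, _ = generate_dataset(46, seed=11)
train_imgs, test_imgs = images[:40], images[40:]

cfg = TrainingConfig(epochs=8, seed=0)
bundle, history = train_cascade(train_imgs, cfg, desk_profile(), seed=1)

print("final training losses per model:")
for name, hist in history.items():
    print(f"  {name:<16} {hist['train_loss'][-1]:.5f}")

print("\nheld-out measurements (PT = pelvic tilt):")
errs = []
for i, ann in enumerate(test_imgs):
    kps = run_cascade(ann.pixels.astype(np.float32), bundle)
    params = compute_all_parameters(kps)
    truth = ann.landmarks.as_dict()
    err = np.mean([np.hypot(p.x - truth[n].x, p.y - truth[n].y)
                   for n, p in kps.as_dict().items()])
    errs.append(err)
    print(f"  case {i}: PT {params.pt:5.1f} deg (truth "
          f"{ann.true_parameters.pt:5.1f}), landmark err {err:4.1f} px")

print(f"\nmean landmark error: {np.mean(errs):.1f} px "
      f"on {test_imgs[0].pixels.shape} images")
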