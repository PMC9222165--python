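"""Static-mode measurement: alpha/beta on a given standard plane.

Renders a noisy phantom standard plane, runs the full measurement chain twice
— once from the ground-truth boxes and once from the bundled heuristic
detector — and compares both against the known true angles.  The differences
are the measurement error of the geometric pipeline itself (segmentation,
baseline fit, landmarks), on the order of 1 degree.
"""

from grafhip import PhantomSpec, render_frame, run_static

frame = render_frame(PhantomSpec(alpha_true=67.0, beta_true=48.0, noise_sigma=5.0, seed=21))
print(f"true angles:     alpha={frame.true_alpha:.2f}  beta={frame.true_beta:.2f}")

oracle = run_static(frame.image, frame.true_boxes)
print(f"oracle boxes:    alpha={oracle.alpha:.2f}  beta={oracle.beta:.2f}  type {oracle.graf_type}")

detected = run_static(frame.image)  # reference detector finds the boxes
print(f"detected boxes:  alpha={detected.alpha:.2f}  beta={detected.beta:.2f}  type {detected.graf_type}")
print("type I means alpha >= 60 deg (mature hip); type II otherwise")
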