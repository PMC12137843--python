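"""Explain model decisions with Grad-CAM.

For the classifier, the map highlights regions supporting the stiff
class. For the regressor, the modified target d = 1/|x - x'| makes the
map highlight regions that would move the prediction toward the
measured value: "decrease" mode when the model overestimates,
"increase" when it underestimates.
"""

import numpy as np

from cellstiff.gradcam import (gradcam_classification,
                               gradcam_regression_modified, overlay_heatmap)
from cellstiff.models import (ClassifierSpec, RegressorSpec, build_classifier,
                              build_regressor, train_model)
from cellstiff.preprocessing import images_to_tensor
from cellstiff.synthetic import PhantomParams, generate_phantom_cell, \
    generate_phantom_spectrum

# quick-trained regressor on a small phantom spectrum
imgs = generate_phantom_spectrum(200, seed=5)
x = images_to_tensor(imgs)
e = np.array([im.modulus_pa for im in imgs])
reg = build_regressor(RegressorSpec(seed=5))
reg, _ = train_model(reg, x[:160], e[:160], x[160:], e[160:], epochs=5,
                     seed=5)

cell = generate_phantom_cell(PhantomParams(s=0.3, seed=99))
pred = float(reg.predict_modulus(images_to_tensor([cell]))[0])
measured = cell.modulus_pa
print(f"predicted {pred:.0f} Pa, measured {measured:.0f} Pa")
sal, ctx = gradcam_regression_modified(reg, cell, x_prime=measured)
print(f"d = 1/|x - x'| = {ctx.d:.2e} /Pa, mode = {ctx.mode}")
print(f"alpha weights per channel: {np.round(sal.alpha, 6)}")

# classifier saliency rendered as a heatmap overlay
clf = build_classifier(ClassifierSpec(seed=5))
sal_c = gradcam_classification(clf, cell, class_c=1)
rendered = overlay_heatmap(sal_c, cell)
print(f"classification map {sal_c.map.shape} upsampled to "
      f"{sal_c.upsampled().shape}; overlay image {rendered.shape}")
# "decrease" mode means the highlighted pixels are the ones the model
# would use to lower its stiffness estimate toward the measurement.
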