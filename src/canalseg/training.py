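"""Semi-supervised training: cross-entropy plus cross-decoder consistency.

Labelled slices train both decoders independently with pixel-averaged
cross-entropy.  Unlabelled slices carry no ground truth, so the two
decoders supervise each other: an L2 penalty between their soft
probability maps (mutual soft pseudo-labelling).  The per-batch
objective is

    loss = CE(decoder A) + CE(decoder B)  on labelled slices
         + lambda * mean((p_A - p_B)^2)   on unlabelled slices

optimised with Adam.  The augmentation suite applies the same spatial
transform (elastic deformation, scaling, rotation) to image and mask
and photometric transforms (Gaussian blur, Gaussian noise) to the
image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, DualDecoderUNet, SegmentationOutput
from .nn.layers import softmax_backward

EPS_CLAMP = 1e-7  # probability clamp inside cross-entropy


# ---------------------------------------------------------------------------
# losses


def supervised_loss(outputs: SegmentationOutput, mask: np.ndarray) -> float:
    """Sum over decoders of the pixel-averaged cross-entropy.

    ``mask`` holds integer class labels (0 = background, 1 = dural sac)
    with shape (H, W) or (N, H, W); probabilities are clamped at
    ``EPS_CLAMP`` for numerical stability.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    n_classes = next(iter(outputs.probs.values())).shape[-1]
    uniq = np.unique(mask)
    if not set(uniq.tolist()) <= set(range(n_classes)):
        raise ValueError(f"mask contains classes {uniq.tolist()} outside 0..{n_classes - 1}")
    onehot = np.eye(n_classes, dtype=np.float64)[mask]
    total = 0.0
    for p in outputs.probs.values():
        pc = np.clip(p, EPS_CLAMP, 1.0)
        total += float(-np.mean((onehot * np.log(pc)).sum(axis=-1)))
    return total


def consistency_loss(prob_a: np.ndarray, prob_b: np.ndarray) -> float:
    """Mean squared difference between two probability maps.

    The mean runs over every element (batch, pixels and class
    channels), so two binary maps that disagree everywhere score 1.0.
    Symmetric; zero iff the maps are identical.
    """
    prob_a, prob_b = np.asarray(prob_a), np.asarray(prob_b)
    if prob_a.shape != prob_b.shape:
        raise ValueError(f"shape mismatch: {prob_a.shape} vs {prob_b.shape}")
    return float(np.mean((prob_a.astype(np.float64) - prob_b) ** 2))


def _supervised_logit_grads(outputs: SegmentationOutput, mask: np.ndarray) -> dict[str, np.ndarray]:
    """d(CE sum)/d(logits) per decoder: (p - onehot) / n_pixels."""
    n_classes = next(iter(outputs.probs.values())).shape[-1]
    onehot = np.eye(n_classes, dtype=np.float32)[mask]
    n_pix = float(np.prod(mask.shape))
    return {k: (p - onehot) / n_pix for k, p in outputs.probs.items()}


def _consistency_logit_grads(outputs: SegmentationOutput, weight: float) -> dict[str, np.ndarray]:
    """d(lambda * mean (pA-pB)^2)/d(logits), through the softmax."""
    pa, pb = outputs.probs["A"], outputs.probs["B"]
    n = float(pa.size)
    diff = (2.0 * weight / n) * (pa - pb)
    return {
        "A": softmax_backward(pa, diff),
        "B": softmax_backward(pb, -diff),
    }


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentParams:
    """Magnitudes and per-transform application probabilities.

    Magnitudes follow common practice for soft-tissue CT segmentation
    (the transforms themselves, not their strengths, are prescribed):
    elastic grid displacement alpha = 10 px smoothed with sigma = 4 px,
    scaling 0.9-1.1, rotation +/-15 degrees, blur sigma up to 1 px,
    additive Gaussian noise with sd 0.05 of the intensity range.
    """

    elastic_alpha_px: float = 10.0
    elastic_sigma_px: float = 4.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.05
    p_elastic: float = 0.5
    p_affine: float = 0.5
    p_blur: float = 0.3
    p_noise: float = 0.3

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(elastic_alpha_px=0.0, scale_range=(1.0, 1.0),
                   rotation_range_deg=(0.0, 0.0), blur_sigma_range=(0.0, 0.0),
                   noise_sd=0.0, p_elastic=0.0, p_affine=0.0, p_blur=0.0, p_noise=0.0)

    def __post_init__(self) -> None:
        for rng_name in ("scale_range", "rotation_range_deg", "blur_sigma_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} is not well-ordered: {(lo, hi)}")
        for p_name in ("p_elastic", "p_affine", "p_blur", "p_noise"):
            if not 0.0 <= getattr(self, p_name) <= 1.0:
                raise ValueError(f"{p_name} must be a probability")


def augment(
    image: np.ndarray,
    mask: np.ndarray | None,
    params: AugmentParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One augmented (image, mask) draw.

    The spatial transform (affine then elastic, composed into a single
    coordinate map) is shared by image (linear interpolation) and mask
    (nearest neighbour, so it stays binary); blur and noise touch the
    image only.  Identity parameters return the inputs unchanged.
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    do_affine = params.p_affine > 0 and rng.random() < params.p_affine
    do_elastic = params.p_elastic > 0 and rng.random() < params.p_elastic
    do_blur = params.p_blur > 0 and rng.random() < params.p_blur
    do_noise = params.p_noise > 0 and rng.random() < params.p_noise

    coords = None
    if do_affine:
        scale = rng.uniform(*params.scale_range)
        angle = np.deg2rad(rng.uniform(*params.rotation_range_deg))
        if scale != 1.0 or angle != 0.0:
            c, s = np.cos(angle), np.sin(angle)
            # inverse map: output pixel -> input pixel, about the centre
            m = np.array([[c, -s], [s, c]]) / scale
            yy, xx = np.meshgrid(np.arange(h, dtype=np.float32),
                                 np.arange(w, dtype=np.float32), indexing="ij")
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            coords = np.stack([
                m[0, 0] * (yy - cy) + m[0, 1] * (xx - cx) + cy,
                m[1, 0] * (yy - cy) + m[1, 1] * (xx - cx) + cx,
            ])
    if do_elastic and params.elastic_alpha_px > 0:
        if coords is None:
            yy, xx = np.meshgrid(np.arange(h, dtype=np.float32),
                                 np.arange(w, dtype=np.float32), indexing="ij")
            coords = np.stack([yy, xx])
        for axis in (0, 1):
            d = rng.uniform(-1.0, 1.0, size=(h, w))
            d = ndimage.gaussian_filter(d, params.elastic_sigma_px, mode="reflect")
            coords[axis] += (params.elastic_alpha_px * d).astype(np.float32)

    out_img, out_mask = image, mask
    if coords is not None:
        out_img = ndimage.map_coordinates(image, coords, order=1, mode="reflect").astype(np.float32)
        if mask is not None:
            out_mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0)
    if do_blur:
        sigma = rng.uniform(*params.blur_sigma_range)
        if sigma > 0:
            out_img = ndimage.gaussian_filter(out_img, sigma).astype(np.float32)
    if do_noise and params.noise_sd > 0:
        span = float(image.max() - image.min()) or 1.0
        out_img = out_img + rng.normal(0.0, params.noise_sd * span, size=out_img.shape).astype(np.float32)
    return out_img, out_mask


# ---------------------------------------------------------------------------
# training loop


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings: Adam, 50 epochs at learning rate 0.001
    (the published schedule); the consistency weight and batch size are
    free parameters with documented defaults."""

    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    consistency_weight: float = 1.0
    augmentation: AugmentParams = field(default_factory=AugmentParams.identity)
    augment_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs >= 1, learning_rate > 0, batch_size >= 1 required")
        if self.consistency_weight < 0:
            raise ValueError("consistency_weight must be non-negative")


def normalize_slice(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance intensity normalisation per slice."""
    image = np.asarray(image, dtype=np.float32)
    return (image - image.mean()) / (image.std() + 1e-6)


def train(
    model: DualDecoderUNet,
    labeled: list[tuple[np.ndarray, np.ndarray]],
    unlabeled: list[np.ndarray],
    config: TrainingConfig,
) -> tuple[DualDecoderUNet, pd.DataFrame]:
    """Run the semi-supervised loop; returns the model and a history table.

    Each optimisation step sees one labelled batch and (when unlabelled
    data exist and lambda > 0) one unlabelled batch of equal size, so
    both loss terms stay active throughout.  With lambda = 0 the result
    is invariant to the unlabelled set.  Fully reproducible for a fixed
    (seed, config, data) triple.
    """
    if not labeled:
        raise ValueError("labelled set must not be empty")
    lam = config.consistency_weight
    use_unlabeled = bool(unlabeled) and lam > 0
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = []
    n_lab = len(labeled)
    u_order: list[int] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_lab)
        sup_vals, cons_vals = [], []
        for start in range(0, n_lab, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, msk = labeled[i]
                if config.augment_enabled:
                    img, msk = augment(img, msk, config.augmentation, rng)
                imgs.append(normalize_slice(img))
                masks.append(np.asarray(msk, dtype=np.int64))
            xb = np.stack(imgs)
            yb = np.stack(masks)
            out = model.forward(xb, phase="train")
            sup_vals.append(supervised_loss(out, yb))
            model.backward(_supervised_logit_grads(out, yb))

            if use_unlabeled:
                uimgs = []
                for _ in range(len(idx)):
                    if not u_order:
                        u_order = list(rng.permutation(len(unlabeled)))
                    uimg = unlabeled[u_order.pop()]
                    if config.augment_enabled:
                        uimg, _ = augment(uimg, None, config.augmentation, rng)
                    uimgs.append(normalize_slice(uimg))
                ub = np.stack(uimgs)
                uout = model.forward(ub, phase="train")
                cons_vals.append(consistency_loss(uout.probs["A"], uout.probs["B"]))
                model.backward(_consistency_logit_grads(uout, lam))
            opt.step()
            opt.zero_grad()
        history.append({
            "epoch": epoch,
            "supervised_loss": float(np.mean(sup_vals)),
            "consistency_loss": float(np.mean(cons_vals)) if cons_vals else 0.0,
        })
    return model, pd.DataFrame(history)


def predict_mask(model: DualDecoderUNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Inference: configured decoder only; dural-sac probability >= threshold."""
    out = model.forward(normalize_slice(image), phase="inference")
    prob = out.probs[model.config.inference_decoder][0, :, :, 1]
    return (prob >= threshold).astype(np.uint8)
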