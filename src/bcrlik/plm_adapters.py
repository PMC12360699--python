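"""Optional adapters exposing real protein language models as providers.

These wrap HuggingFace masked language models behind the
:class:`~bcrlik.likelihood.LikelihoodProvider` contract, scoring one masked
position at a time (true pseudolikelihood) or, with ``single_pass=True``, a
single unmasked forward pass. They require the ``plm`` extra
(``pip install bcrlik[plm]``) and are never needed by the core analyses: any
provider satisfying the contract can drive the pipeline.
"""

from __future__ import annotations

from .errors import ConfigError
from .likelihood import LikelihoodProvider, ProbabilityMatrix


class TransformersMLMProvider(LikelihoodProvider):
    """Masked-LM provider backed by a HuggingFace checkpoint.

    Parameters
    ----------
    model_name:
        Checkpoint id (e.g. an ESM- or antibody-LM-family model).
    single_pass:
        If True, extract all per-position distributions from one unmasked
        forward pass instead of masking each position in turn.
    """

    def __init__(self, model_name: str, single_pass: bool = False):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForMaskedLM, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ConfigError(
                "real PLM adapters require the 'plm' extra (transformers + torch)"
            ) from exc
        self.name = model_name
        self.single_pass = single_pass
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModelForMaskedLM.from_pretrained(model_name)
        self._model.eval()

    def residue_probabilities(self, sequence_aa: str) -> ProbabilityMatrix:  # pragma: no cover
        import numpy as np
        import torch

        from .alphabet import AMINO_ACIDS, N_AA

        tok = self._tokenizer
        aa_ids = [tok.convert_tokens_to_ids(aa) for aa in AMINO_ACIDS]
        enc = tok(" ".join(sequence_aa) if tok.do_lower_case is False else sequence_aa,
                  return_tensors="pt")
        ids = enc["input_ids"]
        # map sequence positions to token positions (skip special tokens)
        special = tok.all_special_ids
        positions = [i for i, t in enumerate(ids[0].tolist()) if t not in special]
        if len(positions) != len(sequence_aa):
            raise ConfigError("tokenizer does not map residues one-to-one")
        probs = np.zeros((len(sequence_aa), N_AA))
        with torch.no_grad():
            if self.single_pass:
                logits = self._model(**enc).logits[0]
                for row, tpos in enumerate(positions):
                    probs[row] = torch.softmax(logits[tpos, aa_ids], dim=-1).numpy()
            else:
                for row, tpos in enumerate(positions):
                    masked = ids.clone()
                    masked[0, tpos] = tok.mask_token_id
                    logits = self._model(input_ids=masked,
                                         attention_mask=enc["attention_mask"]).logits[0]
                    probs[row] = torch.softmax(logits[tpos, aa_ids], dim=-1).numpy()
        return ProbabilityMatrix(sequence_aa, probs)
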