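PY ?= python
OUT ?= runs/synthetic

.PHONY: test reproduce-synthetic clean

test:
	$(PY) -m pytest -q

reproduce-synthetic:
	$(PY) -m bbuda.cli simulate --seed 0 --out $(OUT)/data --force
	$(PY) -m bbuda.cli train-source --data $(OUT)/data --seed 0 --out $(OUT)/source --force
	$(PY) -m bbuda.cli adapt --source-ckpt $(OUT)/source/source_ckpt.npz --data $(OUT)/data --ablation full --seed 0 --out $(OUT)/bbuda --force
	$(PY) -m bbuda.cli adapt --source-ckpt $(OUT)/source/source_ckpt.npz --data $(OUT)/data --ablation no_entropy --seed 0 --out $(OUT)/bbuda_no_ent --force
	$(PY) -m bbuda.cli evaluate --ckpt $(OUT)/bbuda/adapted_ckpt.npz --data $(OUT)/data --out $(OUT)/eval_bbuda --force
	$(PY) -m bbuda.cli evaluate --ckpt $(OUT)/bbuda_no_ent/adapted_ckpt.npz --data $(OUT)/data --out $(OUT)/eval_bbuda_no_ent --force
	$(PY) -m bbuda.cli report $(OUT)/eval_bbuda $(OUT)/eval_bbuda_no_ent

clean:
	rm -rf runs results
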