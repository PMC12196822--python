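# Element-decomposition lexicons for sign-entity standardization.
#
# Tongue entities decompose into six canonical elements (spirit, body
# color, body form, motility, fur color, fur texture) which are recomposed
# in that fixed order, with position/degree modifiers prepended.  The pulse
# inventory below mirrors the same procedure with five elements (position,
# rate, rhythm, strength, shape); it is a reconstruction — the canonical
# source enumerates elements only for the tongue — and is fully editable.

tongue:
  elements:
    spirit: ["荣", "枯"]
    color: ["淡红", "淡白", "红", "绛", "紫", "青"]
    form: ["胖大", "瘦薄", "齿痕", "裂纹", "芒刺", "苍老", "娇嫩"]
    motility: ["强硬", "痿软", "颤动", "歪斜", "短缩"]
    fur_color: ["苔白", "苔黄", "苔灰", "苔黑", "白苔", "黄苔", "灰苔", "黑苔"]
    fur_texture: ["苔厚", "苔薄", "苔腻", "苔燥", "苔滑", "少苔", "无苔"]
  modifiers: ["微", "略", "稍", "甚", "极", "尖", "边", "根", "中"]

pulse:
  elements:
    position: ["浮", "沉", "伏"]
    rate: ["迟", "数", "疾", "缓"]
    rhythm: ["结", "代", "促"]
    strength: ["虚", "实", "微", "弱", "洪"]
    shape: ["滑", "涩", "弦", "紧", "细", "濡", "软", "芤", "革"]
  modifiers: ["略", "稍", "甚", "极", "左", "右", "寸", "关", "尺"]
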