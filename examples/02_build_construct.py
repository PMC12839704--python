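"""Build the graphical construct for one report.

The construct pipeline masks red post-bronchodilator tones, keeps the
bottom half of the page, binarizes and inverts it, drops regions smaller
than 1000 px, closes stroke gaps, keeps the two largest regions (the two
curves), stacks them into a 700 x 500 panel, appends a 200-column frame
whose three sections encode sex/age/BMI as grays, and resizes the
700 x 700 square to the 224 x 224 network input.
"""

from PIL import Image

from spiroqc import (
    Demographics,
    ManeuverParams,
    build_construct,
    render_report,
    simulate_maneuver,
)

maneuver = simulate_maneuver(ManeuverParams(fvc=4.0, pef=8.0))
demo = Demographics(sex="woman", age=45, bmi=18.1)
report = render_report(maneuver, demo, include_post_bd=True)

gc = build_construct(report.page, demo)

vt, fv = gc.intermediates["vt_box"], gc.intermediates["fv_box"]
print(f"volume-time region: {vt.area} px, box {(vt.top, vt.left, vt.bottom, vt.right)}")
print(f"flow-volume region: {fv.area} px, box {(fv.top, fv.left, fv.bottom, fv.right)}")
print(f"frame grays (sex, age, bmi): {gc.frame_grays}")
print("  -> woman = 255; age 45 of [10, 84] -> 121; BMI 18.1 of [15, 54] -> 20")
print(f"network input: {gc.network_input.shape}, dtype {gc.network_input.dtype}")

Image.fromarray(gc.framed).save("scratch/construct_700x700.png")
Image.fromarray(gc.network_input).save("scratch/construct_224x224.png")
print("construct images written to scratch/")
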