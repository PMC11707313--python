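# Synthetic placeholder over-the-counter NRT price schedule (GBP 2021/22).
# The canonical retail price survey behind participants' own NRT spending is
# not redistributable; these values are plausible editable placeholders and
# are flagged NON-CANONICAL. Replace with a local price survey for real use.
item_code,price_gbp,unit_label
otc_nicotine_patch,12.50,pack
otc_nicotine_gum,9.00,pack
otc_nicotine_lozenge,10.50,pack
otc_nicotine_inhalator,1.20,cartridge
otc_nicotine_mouth_spray,14.00,bottle
otc_ecig_device,20.00,device
otc_ecig_liquid,4.00,bottle
otc_ecig_pods,10.00,pack
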