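review_id,research_area,d1,d2,d3,d4,overall
Kelly 2014,physical_activity,low,high,high,high,
Samitz 2011,physical_activity,low,low,high,high,
Woodcock 2011,physical_activity,high,high,unclear,low,
Hupin 2015,physical_activity,low,high,unclear,low,
Biswas 2015,sedentary_behavior,low,high,low,high,
Chau 2013,sedentary_behavior,high,high,low,high,
Grontved 2011,sedentary_behavior,low,high,high,high,
Wilmot 2012,sedentary_behavior,high,high,low,high,
Ford 2012,sedentary_behavior,high,high,high,high,
Pandey 2016,sedentary_behavior,high,high,unclear,unclear,
Sun 2015,sedentary_behavior,high,unclear,high,high,
Costanzo 2011,alcohol,high,high,unclear,high,
Jayasekara 2014,alcohol,low,high,high,high,
Roerecke 2011,alcohol,low,high,high,low,
Roerecke 2014a,alcohol,low,high,high,high,
Ronksley 2011,alcohol,low,low,high,low,
Park 2015,alcohol,high,high,high,high,
Stockwell 2016,alcohol,low,high,unclear,low,
Zheng 2015,alcohol,high,low,low,low,
Roerecke 2010,alcohol,high,high,high,high,
Roerecke 2014b,alcohol,low,high,high,high,
Gellert 2012,smoking,low,unclear,unclear,unclear,
Lv 2015,smoking,low,high,unclear,high,
Sinha 2016,smoking,low,high,high,high,
Farvid 2014,diet,low,high,high,high,
Graudal 2014,diet,low,high,high,high,
Hu 2014,diet,low,high,high,high,
Li 2012,diet,high,high,high,high,
Musa-Veloso 2011,diet,high,high,high,high,
Pan 2012,diet,high,high,low,high,
Poggio 2015,diet,low,high,high,low,
Schwingshackl 2014,diet,low,low,high,high,
Wang 2014,diet,low,high,low,high,
Chen 2016,diet,low,low,low,low,
Cheng 2015,diet,low,high,low,high,
Cheng 2016,diet,low,high,low,high,
De Souza 2015,diet,low,high,high,low,
Narain 2016,diet,low,low,high,low,
Bukkapatnam 2010,statin,high,high,high,high,
Kizer 2010,statin,low,high,high,high,
Kostis 2012,statin,high,high,high,low,
Lv 2014,statin,high,high,high,low,
Ray 2010,statin,high,high,high,high,
Savarese 2013,statin,low,high,low,low,
Taylor 2011,statin,low,low,low,low,
Tonelli 2011,statin,low,high,low,high,
Chou 2016,statin,low,high,low,low,
Preiss 2015,statin,low,high,high,low,
Teng 2015,statin,low,high,low,low,
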