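country,region
China,East Asia and Pacific
Indonesia,East Asia and Pacific
Japan,East Asia and Pacific
Philippines,East Asia and Pacific
Vietnam,East Asia and Pacific
Thailand,East Asia and Pacific
Malaysia,East Asia and Pacific
Australia,East Asia and Pacific
Cambodia,East Asia and Pacific
Mongolia,East Asia and Pacific
New Zealand,East Asia and Pacific
Fiji,East Asia and Pacific
Papua New Guinea,East Asia and Pacific
Germany,Europe and Central Asia
France,Europe and Central Asia
United Kingdom,Europe and Central Asia
Italy,Europe and Central Asia
Spain,Europe and Central Asia
Poland,Europe and Central Asia
Romania,Europe and Central Asia
Netherlands,Europe and Central Asia
Greece,Europe and Central Asia
Portugal,Europe and Central Asia
Sweden,Europe and Central Asia
Hungary,Europe and Central Asia
Austria,Europe and Central Asia
Switzerland,Europe and Central Asia
Bulgaria,Europe and Central Asia
Denmark,Europe and Central Asia
Finland,Europe and Central Asia
Norway,Europe and Central Asia
Turkiye,Europe and Central Asia
Ukraine,Europe and Central Asia
Kazakhstan,Europe and Central Asia
Brazil,Latin America and The Caribbean
Mexico,Latin America and The Caribbean
Colombia,Latin America and The Caribbean
Argentina,Latin America and The Caribbean
Peru,Latin America and The Caribbean
Venezuela,Latin America and The Caribbean
Chile,Latin America and The Caribbean
Ecuador,Latin America and The Caribbean
Guatemala,Latin America and The Caribbean
Cuba,Latin America and The Caribbean
Bolivia,Latin America and The Caribbean
Honduras,Latin America and The Caribbean
Paraguay,Latin America and The Caribbean
Nicaragua,Latin America and The Caribbean
Uruguay,Latin America and The Caribbean
Panama,Latin America and The Caribbean
Egypt,Middle East and North Africa
Iran,Middle East and North Africa
Algeria,Middle East and North Africa
Iraq,Middle East and North Africa
Morocco,Middle East and North Africa
Saudi Arabia,Middle East and North Africa
Yemen,Middle East and North Africa
Tunisia,Middle East and North Africa
Jordan,Middle East and North Africa
Lebanon,Middle East and North Africa
United States,North America
Canada,North America
India,South Asia
Pakistan,South Asia
Bangladesh,South Asia
Nepal,South Asia
Sri Lanka,South Asia
Nigeria,Sub-Saharan Africa
Ethiopia,Sub-Saharan Africa
Democratic Republic of the Congo,Sub-Saharan Africa
Tanzania,Sub-Saharan Africa
South Africa,Sub-Saharan Africa
Kenya,Sub-Saharan Africa
Uganda,Sub-Saharan Africa
Sudan,Sub-Saharan Africa
Angola,Sub-Saharan Africa
Ghana,Sub-Saharan Africa
Mozambique,Sub-Saharan Africa
Madagascar,Sub-Saharan Africa
Cameroon,Sub-Saharan Africa
Niger,Sub-Saharan Africa
Mali,Sub-Saharan Africa
Burkina Faso,Sub-Saharan Africa
Malawi,Sub-Saharan Africa
Zambia,Sub-Saharan Africa
Senegal,Sub-Saharan Africa
Chad,Sub-Saharan Africa
Zimbabwe,Sub-Saharan Africa
Rwanda,Sub-Saharan Africa
Benin,Sub-Saharan Africa
Guinea,Sub-Saharan Africa
Somalia,Sub-Saharan Africa
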